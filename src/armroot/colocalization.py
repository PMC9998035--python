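"""Genomic co-localization of complex subunit genes.

A single horizontal transfer of a whole complex would most plausibly move a
physically clustered block of subunit genes, so present-day clustering (or
its absence) is evidence about transfer plausibility.  Species are classed
by how their subunit loci distribute over scaffolds, and same-scaffold gene
pairs are measured by their intergenic gap.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .io import ArmrootError

CLASSES = ("all_distinct", "partial_shared", "single_scaffold", "insufficient")


@dataclass
class ScaffoldSummary:
    per_species: pd.DataFrame  # species, n_loci, n_scaffolds, class
    class_counts: dict

    @property
    def n_sufficient(self):
        return sum(
            v for k, v in self.class_counts.items() if k != "insufficient"
        )


def scaffold_sharing_summary(loci, subunits=None):
    """Classify each species by scaffold sharing among its subunit loci.

    ``all_distinct``: every locus on its own scaffold; ``single_scaffold``:
    all on one; ``partial_shared``: in between.  Species with fewer than two
    loci are reported as ``insufficient`` rather than classified.
    """
    df = loci
    if subunits is not None:
        df = df[df["subunit"].isin(set(subunits))]
    rows = []
    for sp, block in df.groupby("species", sort=True):
        n = len(block)
        k = block["scaffold"].nunique()
        if n < 2:
            cls = "insufficient"
        elif k == n:
            cls = "all_distinct"
        elif k == 1:
            cls = "single_scaffold"
        else:
            cls = "partial_shared"
        rows.append((sp, n, k, cls))
    per_species = pd.DataFrame(
        rows, columns=["species", "n_loci", "n_scaffolds", "class"]
    )
    counts = {c: int((per_species["class"] == c).sum()) for c in CLASSES}
    return ScaffoldSummary(per_species=per_species, class_counts=counts)


def same_scaffold_distances(loci):
    """Intergenic gaps for every same-scaffold locus pair, per species.

    The distance between two loci is ``max(0, later.start − earlier.end)``
    (0 with an overlap flag for overlapping genes).  Returns (pair table,
    overall mean gap) — the mean is NaN when no pair shares a scaffold.
    """
    rows = []
    for (sp, scaf), block in loci.groupby(["species", "scaffold"], sort=True):
        recs = block.sort_values("start").to_dict("records")
        for a, b in combinations(recs, 2):
            first, second = (a, b) if a["start"] <= b["start"] else (b, a)
            gap = second["start"] - first["end"]
            overlap = gap < 0
            rows.append(
                (sp, scaf, first["subunit"], second["subunit"],
                 max(0, gap), overlap)
            )
    pairs = pd.DataFrame(
        rows,
        columns=["species", "scaffold", "subunit_a", "subunit_b", "gap_bp",
                 "overlap"],
    )
    mean_gap = float(pairs["gap_bp"].mean()) if len(pairs) else float("nan")
    return pairs, mean_gap


@dataclass
class ColocalizationVerdict:
    verdict: str  # "clustered" | "dispersed"
    frac_single_scaffold: float
    mean_gap_bp: float
    majority_threshold: float
    max_mean_gap_bp: float

    def report(self):
        return (
            f"verdict: {self.verdict}\n"
            f"single-scaffold species fraction: {self.frac_single_scaffold:.3f} "
            f"(clustered requires > {self.majority_threshold})\n"
            f"mean same-scaffold gap: {self.mean_gap_bp:.0f} bp "
            f"(clustered requires <= {self.max_mean_gap_bp:.0f} bp)\n"
        )


def colocalization_verdict(summary, mean_gap_bp, majority_threshold=0.5,
                           max_mean_gap_bp=100_000):
    """Declare "clustered" only if a majority of classifiable species are
    single-scaffold AND the mean same-scaffold gap is below the threshold;
    otherwise "dispersed".  Thresholds are echoed in the result."""
    n = summary.n_sufficient
    if n == 0:
        raise ArmrootError("no species with >= 2 loci to classify")
    frac_single = summary.class_counts["single_scaffold"] / n
    clustered = frac_single > majority_threshold and (
        not np.isnan(mean_gap_bp) and mean_gap_bp <= max_mean_gap_bp
    )
    return ColocalizationVerdict(
        verdict="clustered" if clustered else "dispersed",
        frac_single_scaffold=frac_single,
        mean_gap_bp=mean_gap_bp,
        majority_threshold=majority_threshold,
        max_mean_gap_bp=max_mean_gap_bp,
    )
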