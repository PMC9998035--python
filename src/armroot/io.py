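"""Readers/writers for the pipeline's external formats plus run configuration.

Formats: FASTA (sequences and alignments), newick trees, presence/absence
TSV, profile-vs-profile E-value TSV, BED-like locus TSV, and the Cα subset
of PDB files.  All readers validate and *reject* malformed input instead of
repairing it; error messages carry file (and where possible line) context.
"""

from __future__ import annotations

import hashlib
import io as _io
from dataclasses import dataclass, field, fields

import dendropy
import gemmi
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "ArmrootError",
    "FormatError",
    "AnalysisConfig",
    "SpeciesTable",
    "MAJOR_GROUPS",
    "read_fasta",
    "write_fasta",
    "read_newick",
    "write_newick",
    "read_presence_tsv",
    "write_presence_tsv",
    "read_evalue_tsv",
    "read_loci_tsv",
    "write_loci_tsv",
    "read_pdb_ca",
    "read_species_tsv",
    "load_config",
    "provenance_block",
]


class ArmrootError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(ArmrootError):
    """Malformed input file; message includes file and line context."""

    def __init__(self, message, path=None, line=None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line


# The nine eukaryotic major groups used as the default controlled vocabulary
# for species annotations.
MAJOR_GROUPS = (
    "Amorphea",
    "CRuMs",
    "Discoba",
    "Metamonada",
    "Hemimastigophora",
    "TSAR",
    "Cryptista",
    "Haptista",
    "Archaeplastida",
)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path):
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are upper-cased and ``.`` gap characters normalised to ``-``.
    Duplicate ids and empty files are errors.
    """
    records = {}
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if rec.id in records:
            raise FormatError(f"duplicate sequence id {rec.id!r} (record {i})", path)
        records[rec.id] = str(rec.seq).upper().replace(".", "-")
    if not records:
        raise FormatError("no FASTA records found", path)
    return records


def write_fasta(records, path, width=60):
    """Write ``{id: sequence}`` to *path*; returns *path*."""
    if not records:
        raise ArmrootError("refusing to write an empty FASTA file")
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# Newick


def _attach_supports(tree):
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            try:
                node.support = float(node.label)
            except ValueError:
                pass


def read_newick(source, rooted=False):
    """Parse a newick tree (file path or string) into a dendropy ``Tree``.

    With ``rooted=True`` a degree-2 root is preserved.  Numeric internal
    node labels are additionally attached as ``node.support``.
    """
    if isinstance(source, str) and (
        source.lstrip().startswith("(") or source.rstrip().endswith(";")
    ):
        src, path = {"data": source}, "<string>"
    else:
        src, path = {"path": str(source)}, source
    try:
        tree = dendropy.Tree.get(
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="force-rooted" if rooted else "default-unrooted",
            **src,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"newick parse error: {exc}", path) from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if len(labels) != len(set(labels)):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise FormatError(f"duplicate leaf labels: {', '.join(dup)}", path)
    _attach_supports(tree)
    return tree


def write_newick(tree, path=None):
    """Serialise a tree to newick text (branch lengths at 12 significant
    digits); optionally also write it to *path*."""
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".12g",
    ).strip() + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Presence/absence TSV

_PRESENT_TOKENS = {"1", "yes", "y", "true", "present"}
_ABSENT_TOKENS = {"0", "no", "n", "false", "absent"}
_UNKNOWN_TOKENS = {"na", "nan", "?", "unknown", ""}


def read_presence_tsv(path, complexes=None, conditioning_gene="Ndc80"):
    """Read a species × subunit presence table.

    Cells accept ``1/0/yes/no/NA`` (case-insensitive); ``NA`` maps to the
    *unknown* state, which downstream code keeps out of denominators.
    Returns a :class:`armroot.profiles.PresenceMatrix`.
    """
    from .profiles import PresenceMatrix, default_complexes

    rows, species = [], []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise FormatError("presence table needs >= 1 subunit column", path, 1)
        subunits = header[1:]
        if len(set(subunits)) != len(subunits):
            raise FormatError("duplicate subunit columns", path, 1)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"expected {len(header)} columns, got {len(parts)}", path, lineno
                )
            sp, cells = parts[0], parts[1:]
            if sp in species:
                raise FormatError(f"duplicate species {sp!r}", path, lineno)
            coded = []
            for subunit, cell in zip(subunits, cells):
                tok = cell.strip().lower()
                if tok in _PRESENT_TOKENS:
                    coded.append(1)
                elif tok in _ABSENT_TOKENS:
                    coded.append(0)
                elif tok in _UNKNOWN_TOKENS:
                    coded.append(-1)
                else:
                    raise FormatError(
                        f"unparseable presence cell {cell!r} for {sp}/{subunit}",
                        path,
                        lineno,
                    )
            species.append(sp)
            rows.append(coded)
    if not rows:
        raise FormatError("presence table has no species rows", path)
    data = pd.DataFrame(rows, index=species, columns=subunits, dtype="int8")
    if complexes is None:
        complexes = default_complexes(subunits)
    return PresenceMatrix(data=data, complexes=complexes, conditioning_gene=conditioning_gene)


def write_presence_tsv(matrix, path):
    """Write a PresenceMatrix back to TSV (1/0/NA cells)."""
    df = matrix.data.replace({1: "1", 0: "0", -1: "NA"})
    df.to_csv(path, sep="\t", index_label="species")
    return path


# ---------------------------------------------------------------------------
# E-value TSV


def read_evalue_tsv(path):
    """Read a query × target E-value matrix (floats, scientific notation ok).

    Empty cells become NaN ("no hit"); negative E-values are rejected.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        targets = header[1:]
        if not targets:
            raise FormatError("E-value table needs >= 1 target column", path, 1)
        queries, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise FormatError(
                    f"expected {len(header)} columns, got {len(parts)}", path, lineno
                )
            vals = []
            for tgt, cell in zip(targets, parts[1:]):
                tok = cell.strip()
                if tok in ("", "NA", "nan"):
                    vals.append(float("nan"))
                    continue
                try:
                    v = float(tok)
                except ValueError:
                    raise FormatError(
                        f"non-numeric E-value {cell!r} for {parts[0]}->{tgt}",
                        path,
                        lineno,
                    ) from None
                if v < 0:
                    raise FormatError(
                        f"negative E-value {v} for {parts[0]}->{tgt}", path, lineno
                    )
                vals.append(v)
            queries.append(parts[0])
            rows.append(vals)
    if not rows:
        raise FormatError("E-value table has no rows", path)
    return pd.DataFrame(rows, index=queries, columns=targets, dtype=float)


# ---------------------------------------------------------------------------
# Locus TSV (BED-like; 0-based half-open coordinates)

_LOCUS_COLUMNS = ["species", "subunit", "scaffold", "start", "end", "strand"]


def read_loci_tsv(path):
    """Read a gene-locus table with 0-based half-open [start, end) intervals."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != _LOCUS_COLUMNS:
            raise FormatError(
                f"locus table header must be {_LOCUS_COLUMNS}, got {header}", path, 1
            )
        rows = []
        seen = set()
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise FormatError(f"expected 6 columns, got {len(parts)}", path, lineno)
            sp, su, scaf, start, end, strand = parts
            try:
                start, end = int(start), int(end)
            except ValueError:
                raise FormatError("non-integer locus coordinate", path, lineno) from None
            if end <= start:
                raise FormatError(f"end {end} <= start {start}", path, lineno)
            if strand not in {"+", "-", "."}:
                raise FormatError(f"bad strand {strand!r}", path, lineno)
            if (sp, su) in seen:
                raise FormatError(f"duplicate locus for ({sp}, {su})", path, lineno)
            seen.add((sp, su))
            rows.append((sp, su, scaf, start, end, strand))
    if not rows:
        raise FormatError("locus table has no rows", path)
    return pd.DataFrame(rows, columns=_LOCUS_COLUMNS)


def write_loci_tsv(loci, path):
    loci.to_csv(path, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# PDB Cα subset


def read_pdb_ca(path, chain):
    """Extract the ordered Cα trace of one chain from a PDB file.

    Returns a :class:`armroot.superpose.CoordSet` ordered by residue number;
    for altLoc duplicates the first conformer is kept.  1-based residue
    numbering from the file is preserved.
    """
    from .superpose import CoordSet

    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except Exception as exc:
        raise FormatError(f"PDB parse error: {exc}", path) from exc
    if len(structure) == 0:
        raise FormatError("PDB file contains no models", path)
    model = structure[0]
    names = [ch.name for ch in model]
    if chain not in names:
        raise FormatError(f"chain {chain!r} not found (have: {', '.join(names)})", path)
    coords, resids, seq = [], [], []
    for residue in model[chain]:
        ca = None
        for atom in residue:
            if atom.name == "CA":
                ca = atom
                break  # first altLoc wins
        if ca is None:
            continue
        coords.append((ca.pos.x, ca.pos.y, ca.pos.z))
        resids.append(residue.seqid.num)
        info = gemmi.find_tabulated_residue(residue.name)
        seq.append(info.one_letter_code.upper() if info else "X")
    if not coords:
        raise FormatError(f"chain {chain!r} has no CA atoms", path)
    order = sorted(range(len(resids)), key=lambda i: resids[i])
    return CoordSet(
        coords=[coords[i] for i in order],
        residue_ids=[resids[i] for i in order],
        chain_id=chain,
        sequence="".join(seq[i] for i in order),
    )


# ---------------------------------------------------------------------------
# Species annotation table


@dataclass
class SpeciesTable:
    """Species annotations: display name, major group, taxon, data type.

    BUSCO-style completeness values, if present, are carried as opaque
    annotations in extra columns and never interpreted.
    """

    data: pd.DataFrame
    groups: tuple = MAJOR_GROUPS

    def __post_init__(self):
        required = {"species", "name", "group", "taxon", "data_type"}
        missing = required - set(self.data.columns)
        if missing:
            raise ArmrootError(f"species table missing columns: {sorted(missing)}")
        if self.data["species"].duplicated().any():
            dup = self.data.loc[self.data["species"].duplicated(), "species"].tolist()
            raise ArmrootError(f"duplicate species ids: {dup}")
        bad_group = set(self.data["group"]) - set(self.groups)
        if bad_group:
            raise ArmrootError(
                f"group labels outside controlled vocabulary: {sorted(bad_group)}"
            )
        bad_type = set(self.data["data_type"]) - {"genome", "transcriptome"}
        if bad_type:
            raise ArmrootError(f"bad data_type values: {sorted(bad_type)}")

    def group_of(self, species):
        row = self.data.loc[self.data["species"] == species]
        if row.empty:
            raise ArmrootError(f"species {species!r} not in species table")
        return row["group"].iloc[0]


def read_species_tsv(path, groups=MAJOR_GROUPS):
    df = pd.read_csv(path, sep="\t", dtype=str)
    return SpeciesTable(data=df, groups=tuple(groups))


# ---------------------------------------------------------------------------
# Configuration & provenance

#: Substitution-model names reported by the published analysis this pipeline
#: re-implements at desk scale; recorded verbatim in provenance output while
#: the executed model is the configured one.
REFERENCE_MODEL_NAMES = ("LG+F+R5", "VT+F+R7")


@dataclass
class AnalysisConfig:
    """All tunable thresholds and model settings for a pipeline run.

    Defaults follow the study's stated rules: ortholog-inclusion E-value
    1e-3, homology-network E-value 10, dataset inclusion at >= 4 detected
    subunits, arm-supermatrix inclusion at >= 2 subunits per arm, and
    gap-threshold trimming keeping columns with >= 5% residues.
    """

    evalue_inclusion_threshold: float = 1e-3
    evalue_network_threshold: float = 10.0
    min_subunits_for_species_inclusion: int = 4
    min_subunits_per_arm: int = 2
    trim_keep_fraction: float = 0.05
    rng_seed: int = 0
    substitution_model: str = "POISSON"  # POISSON | LG
    frequency_mode: str = "MODEL"  # MODEL | EMPIRICAL
    rate_model: str = "UNIFORM"  # UNIFORM | GAMMA
    gamma_classes: int = 4
    gamma_alpha: float = 1.0
    rell_replicates: int = 1000
    au_scales: tuple = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0, 1.1, 1.2, 1.3, 1.4)

    def __post_init__(self):
        if self.evalue_inclusion_threshold <= 0 or self.evalue_network_threshold <= 0:
            raise ArmrootError("E-value thresholds must be positive")
        if not (0 < self.trim_keep_fraction <= 1):
            raise ArmrootError("trim_keep_fraction must be in (0, 1]")
        if self.min_subunits_for_species_inclusion < 1 or self.min_subunits_per_arm < 1:
            raise ArmrootError("minimum subunit counts must be >= 1")
        scales = tuple(float(s) for s in self.au_scales)
        if any(b <= a for a, b in zip(scales, scales[1:])):
            raise ArmrootError("au_scales must be strictly increasing")
        if 1.0 not in scales:
            raise ArmrootError("au_scales must contain 1.0")
        self.au_scales = scales
        if self.substitution_model not in {"POISSON", "LG"}:
            raise ArmrootError(f"unknown substitution model {self.substitution_model!r}")
        if self.frequency_mode not in {"MODEL", "EMPIRICAL"}:
            raise ArmrootError(f"unknown frequency mode {self.frequency_mode!r}")
        if self.rate_model not in {"UNIFORM", "GAMMA"}:
            raise ArmrootError(f"unknown rate model {self.rate_model!r}")
        if self.rell_replicates < 1:
            raise ArmrootError("rell_replicates must be >= 1")


def load_config(path):
    """Load an AnalysisConfig from a flat YAML key/value document."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError("config must be a flat key/value mapping", path)
    known = {f.name for f in fields(AnalysisConfig)}
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}", path)
    if "au_scales" in raw:
        raw["au_scales"] = tuple(raw["au_scales"])
    return AnalysisConfig(**raw)


def provenance_block(config, input_paths=()):
    """Render a reproducibility block: config, seed, and input digests."""
    buf = _io.StringIO()
    buf.write("# provenance\n")
    for f in fields(config):
        buf.write(f"{f.name}: {getattr(config, f.name)}\n")
    buf.write(f"reference_models: {', '.join(REFERENCE_MODEL_NAMES)}\n")
    for p in input_paths:
        h = hashlib.sha256(open(p, "rb").read()).hexdigest()[:16]
        buf.write(f"input: {p} sha256:{h}\n")
    return buf.getvalue()
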