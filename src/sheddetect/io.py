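"""Tabular I/O and the shared data model.

All pipeline stages exchange four container types: :class:`ExpressionMatrix`
(samples x features), :class:`SampleDesign` (condition labels),
:class:`FeatureAnnotation` (protein->gene map plus UniProt-style subcellular
location and membrane topology), and :class:`GeneSetLibrary` (GMT gene
sets).  Files are plain TSV/CSV with one header row; expression tables may
be stored features-in-rows (the common public format) and are transposed on
read.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MATRIX_KINDS = ("counts", "intensities", "log_intensities")

#: Membrane topology classes, ordered roughly by how amenable the class is
#: to ectodomain shedding (single-pass ectodomains first).
TOPOLOGY_CLASSES = (
    "single_pass_I",
    "single_pass_II",
    "single_pass_III",
    "single_pass_IV",
    "single_pass_unknown",
    "multi_pass",
    "gpi_anchor",
    "none",
)

#: Substring keywords (lower-case) that mark a protein as cell-surface.
DEFAULT_SURFACE_KEYWORDS = ("cell membrane", "cell surface")


class TableFormatError(ValueError):
    """Raised when an input table violates the format contract."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """A samples x features numeric matrix with ids and a kind tag.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_features)
        Raw counts, reporter intensities, or log2 intensities depending on
        ``kind``.
    sample_ids, feature_ids : sequence of str
        Unique identifiers for rows and columns.
    kind : {"counts", "intensities", "log_intensities"}
    """

    values: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    kind: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        if self.kind not in MATRIX_KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        n, p = self.values.shape
        if n != len(self.sample_ids) or p != len(self.feature_ids):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        finite = np.isfinite(self.values)
        missing = np.isnan(self.values)
        if not (finite | missing).all():
            raise ValueError("expression values must be finite (or NaN for missing)")
        if missing.any():
            if self.kind == "counts":
                raise ValueError("count matrices may not contain missing values")
            logger.warning(
                "%d missing values in %s matrix (%.2f%%); downstream tests are df-aware",
                missing.sum(), self.kind, 100 * missing.mean(),
            )
        if self.kind == "counts":
            if (self.values < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(self.values, np.round(self.values)):
                bad = np.argwhere(~np.isclose(self.values, np.round(self.values)))[0]
                raise ValueError(
                    f"counts must be integers; first non-integer at sample "
                    f"{self.sample_ids[bad[0]]!r}, feature {self.feature_ids[bad[1]]!r}"
                )
        elif self.kind == "intensities" and self.values.size and not missing.all():
            if np.nanmin(self.values) < 0:
                raise ValueError("intensities must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(
            self.values[idx, :], list(sample_ids), list(self.feature_ids), self.kind
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionMatrix":
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        idx = [pos[f] for f in feature_ids]
        return ExpressionMatrix(
            self.values[:, idx], list(self.sample_ids), list(feature_ids), self.kind
        )

    def feature_index(self, feature_id: str) -> int:
        return self.feature_ids.index(feature_id)


@dataclass
class SampleDesign:
    """Maps sample ids to experimental condition (control vs knockdown)."""

    table: pd.DataFrame  # columns: sample_id, condition, (batch)

    CONDITIONS = ("control", "knockdown")

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "condition"):
            if col not in t.columns:
                raise TableFormatError(f"design table lacks column {col!r}")
        _check_unique(list(t["sample_id"]), "sample")
        bad = set(t["condition"]) - set(self.CONDITIONS)
        if bad:
            raise TableFormatError(f"unknown conditions {sorted(bad)}; expected {self.CONDITIONS}")
        counts = t["condition"].value_counts()
        for cond in self.CONDITIONS:
            if counts.get(cond, 0) < 2:
                raise TableFormatError(f"condition {cond!r} has fewer than 2 samples")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, str]) -> "SampleDesign":
        return cls(pd.DataFrame({"sample_id": list(mapping), "condition": list(mapping.values())}))

    def condition_of(self, sample_id: str) -> str:
        row = self.table.loc[self.table["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(sample_id)
        return row["condition"].iloc[0]

    def samples(self, condition: str) -> list[str]:
        return list(self.table.loc[self.table["condition"] == condition, "sample_id"])

    def membership(self, sample_ids: Sequence[str]) -> np.ndarray:
        """0/1 indicator (1 = knockdown) aligned to ``sample_ids``."""
        lut = dict(zip(self.table["sample_id"], self.table["condition"]))
        missing = [s for s in sample_ids if s not in lut]
        if missing:
            raise KeyError(f"samples absent from design: {missing}")
        return np.array([1 if lut[s] == "knockdown" else 0 for s in sample_ids])

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        known = set(self.table["sample_id"])
        missing = [s for s in matrix.sample_ids if s not in known]
        if missing:
            raise TableFormatError(f"matrix samples missing from design: {missing}")


@dataclass
class FeatureAnnotation:
    """Protein->gene mapping with subcellular location and topology.

    ``is_surface`` is derived from the location string by case-insensitive
    substring match against a configurable keyword list (default:
    "Cell membrane", "Cell surface").  Multi-location strings count as
    surface if any surface keyword is present; the call is logged so the
    adjudication is auditable.
    """

    table: pd.DataFrame  # protein_id, gene_id, subcellular_location, topology, is_surface
    surface_keywords: tuple[str, ...] = DEFAULT_SURFACE_KEYWORDS

    def __post_init__(self) -> None:
        needed = {"protein_id", "gene_id", "subcellular_location", "topology", "is_surface"}
        missing = needed - set(self.table.columns)
        if missing:
            raise TableFormatError(f"annotation lacks columns {sorted(missing)}")
        _check_unique(list(self.table["protein_id"]), "protein")
        bad = set(self.table["topology"]) - set(TOPOLOGY_CLASSES)
        if bad:
            raise TableFormatError(f"unknown topology classes {sorted(bad)}")

    def gene_of(self) -> dict[str, str]:
        return dict(zip(self.table["protein_id"], self.table["gene_id"]))

    def row(self, protein_id: str) -> pd.Series:
        sel = self.table.loc[self.table["protein_id"] == protein_id]
        if sel.empty:
            raise KeyError(protein_id)
        return sel.iloc[0]


@dataclass
class GeneSetLibrary:
    """Named gene sets (GMT dialect: name, description, genes...)."""

    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise TableFormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise TableFormatError(f"gene set {name!r} has duplicate genes")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


# ---------------------------------------------------------------------------
# parsing helpers
# ---------------------------------------------------------------------------


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    dups = []
    for x in ids:
        seen[x] = seen.get(x, 0) + 1
    dups = sorted(x for x, c in seen.items() if c > 1)
    if dups:
        raise TableFormatError(f"duplicate {what} ids: {dups}")


_TOPOLOGY_PATTERNS = (
    (r"single-pass\s+type\s+i\b", "single_pass_I"),
    (r"single-pass\s+type\s+ii\b", "single_pass_II"),
    (r"single-pass\s+type\s+iii\b", "single_pass_III"),
    (r"single-pass\s+type\s+iv\b", "single_pass_IV"),
    (r"single-pass", "single_pass_unknown"),
    (r"multi-?pass", "multi_pass"),
    (r"gpi-anchor", "gpi_anchor"),
    (r"lipid-anchor", "gpi_anchor"),
)


def parse_topology(topology_string: str, location_string: str = "") -> str:
    """Parse a UniProt-style topology description into a topology class.

    GPI anchoring is annotated by UniProt inside the location string
    ("Lipid-anchor, GPI-anchor"), so the location is consulted when the
    topology field itself is empty.
    """
    stripped = (topology_string or "").strip()
    if stripped in TOPOLOGY_CLASSES:  # already-canonical token (round-trip)
        return stripped
    text = stripped.lower()
    # UniProt writes "type I" before "type II" patterns match; order matters.
    for pattern, cls in _TOPOLOGY_PATTERNS:
        if re.search(pattern, text):
            if cls == "single_pass_II" and re.search(r"type\s+iii", text):
                continue
            return cls
    loc = (location_string or "").lower()
    if re.search(r"gpi-anchor", loc):
        return "gpi_anchor"
    if not text:
        return "none"
    logger.warning("unrecognized topology string %r; recording as single_pass_unknown", topology_string)
    return "single_pass_unknown"


def is_surface_location(
    location_string: str,
    keywords: Iterable[str] = DEFAULT_SURFACE_KEYWORDS,
) -> bool:
    """True iff the location string contains a surface keyword (case-insensitive)."""
    loc = (location_string or "").lower()
    return any(k.lower() in loc for k in keywords)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            return "\t" if "\t" in line else ","
    raise TableFormatError(f"{path}: empty file")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _sniff_sep(path)
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, index_col=0,
                       keep_default_na=False)


def read_expression_table(
    path: str | Path,
    kind: str,
    orientation: str = "features_in_rows",
) -> ExpressionMatrix:
    """Read a delimited expression table into samples-in-rows orientation.

    Parameters
    ----------
    orientation : {"samples_in_rows", "features_in_rows"}
        Orientation of the *file*; the returned matrix is always
        samples x features.
    """
    if orientation not in ("samples_in_rows", "features_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path)
    missing_tokens = {"", "na", "nan"}
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            token = "" if raw is None else str(raw).strip()
            if token.lower() in missing_tokens:
                if kind == "counts":
                    raise TableFormatError(
                        f"{path}: non-numeric cell {token!r} at row {df.index[i]!r}, "
                        f"column {col!r}"
                    )
                values[i, j] = np.nan  # missing intensity, permitted and flagged
                continue
            try:
                values[i, j] = float(token)
            except (TypeError, ValueError):
                raise TableFormatError(
                    f"{path}: non-numeric cell {raw!r} at row {df.index[i]!r}, "
                    f"column {col!r}"
                ) from None
    if orientation == "features_in_rows":
        values = values.T
        sample_ids, feature_ids = list(df.columns), list(df.index)
    else:
        sample_ids, feature_ids = list(df.index), list(df.columns)
    if kind == "counts" and values.size and np.nanmin(values) < 0:
        i, j = map(int, np.argwhere(values < 0)[0])
        raise TableFormatError(
            f"{path}: negative count at sample {sample_ids[i]!r}, feature {feature_ids[j]!r}"
        )
    return ExpressionMatrix(values, sample_ids, feature_ids, kind)


def _header_comment(config_hash: str | None) -> str:
    from . import __version__

    tag = f"# sheddetect v{__version__}"
    if config_hash:
        tag += f" config={config_hash}"
    return tag + "\n"


def write_expression_table(
    matrix: ExpressionMatrix,
    path: str | Path,
    orientation: str = "features_in_rows",
    config_hash: str | None = None,
) -> None:
    """Write an expression matrix as TSV with a provenance comment line."""
    df = matrix.to_frame()
    if orientation == "features_in_rows":
        df = df.T
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        df.to_csv(fh, sep="\t", float_format="%.17g")


def write_result_table(df: pd.DataFrame, path: str | Path, config_hash: str | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(config_hash))
        df.to_csv(fh, sep="\t", index=False, float_format="%.12g")


def read_design_table(path: str | Path) -> SampleDesign:
    df = _read_table(path).reset_index()
    df.columns = [c.strip() for c in df.columns]
    return SampleDesign(df)


def read_annotation_table(
    path: str | Path,
    surface_keywords: Iterable[str] = DEFAULT_SURFACE_KEYWORDS,
) -> FeatureAnnotation:
    """Read a protein annotation table and derive topology / surface flags."""
    df = _read_table(path).reset_index()
    needed = {"protein_id", "gene_id", "subcellular_location", "topology"}
    missing = needed - set(df.columns)
    if missing:
        raise TableFormatError(f"{path}: annotation lacks columns {sorted(missing)}")
    return build_annotation(
        df["protein_id"],
        df["gene_id"],
        df["subcellular_location"].fillna(""),
        df["topology"].fillna(""),
        surface_keywords=surface_keywords,
    )


def build_annotation(
    protein_ids: Sequence[str],
    gene_ids: Sequence[str],
    locations: Sequence[str],
    topologies: Sequence[str],
    surface_keywords: Iterable[str] = DEFAULT_SURFACE_KEYWORDS,
) -> FeatureAnnotation:
    keywords = tuple(surface_keywords)
    parsed = [parse_topology(t, l) for t, l in zip(topologies, locations)]
    surface = [is_surface_location(l, keywords) for l in locations]
    for prot, loc, surf in zip(protein_ids, locations, surface):
        if surf and ";" in str(loc):
            logger.debug("multi-location %r adjudicated as surface: %r", prot, loc)
    table = pd.DataFrame(
        {
            "protein_id": [str(p) for p in protein_ids],
            "gene_id": [str(g) for g in gene_ids],
            "subcellular_location": [str(l) for l in locations],
            "topology": parsed,
            "is_surface": surface,
        }
    )
    return FeatureAnnotation(table, surface_keywords=keywords)


def write_annotation_table(annotation: FeatureAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(None))
        annotation.table.to_csv(fh, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetLibrary:
    """Read a Broad-dialect GMT file: name TAB description TAB gene..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    n_lines = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise TableFormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, need >= 3"
                )
            name, desc = fields[0], fields[1]
            genes: list[str] = []
            seen: set[str] = set()
            for g in fields[2:]:
                g = g.strip()
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            sets[name] = genes
            descriptions[name] = desc
    if n_lines == 0:
        raise TableFormatError(f"{path}: empty GMT file")
    return GeneSetLibrary(sets, descriptions)


def write_gmt(library: GeneSetLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in library:
            desc = library.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")
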