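"""Reading, validating and joining plate count data and sample metadata.

Count matrices arrive in the sparse triplet layout written by Cell Ranger
and STARsolo (``matrix.mtx`` + ``features.tsv`` + ``barcodes.tsv``,
optionally gzipped); sample sheets are delimited text keyed by well
barcode.  The two are joined on barcode into a :class:`Screen`, the object
every downstream stage consumes.
"""

from __future__ import annotations

import gzip
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

__all__ = [
    "CountMatrix",
    "PlateMetadata",
    "Screen",
    "ValidationReport",
    "REQUIRED_COLUMNS",
    "DEFAULT_SYNONYMS",
    "read_count_triplet",
    "write_count_triplet",
    "read_metadata",
    "write_metadata",
    "validate_metadata",
    "assemble_screen",
]

#: Minimal sample-sheet schema.  ``sample_type`` distinguishes perturbed
#: wells from solvent-only (vehicle) wells that serve as the DE baseline.
REQUIRED_COLUMNS = (
    "barcode",
    "well",
    "treatment",
    "concentration",
    "unit",
    "sample_type",
    "replicate",
    "plate",
)

SAMPLE_TYPES = ("treatment", "vehicle", "positive_control", "empty")

#: Case-insensitive header synonyms applied by :func:`read_metadata`.
DEFAULT_SYNONYMS: dict[str, str] = {
    "sample_barcode": "barcode",
    "cell_barcode": "barcode",
    "well_id": "well",
    "compound": "treatment",
    "drug": "treatment",
    "conc": "concentration",
    "dose": "concentration",
    "concentration_unit": "unit",
    "conc_unit": "unit",
    "type": "sample_type",
    "rep": "replicate",
    "plate_id": "plate",
    "plate_barcode": "plate",
}

#: Characters allowed in identifier columns; treatment strings become file
#: names downstream, so anything outside this set is flagged.
IDENTIFIER_PATTERN = re.compile(r"^[A-Za-z0-9._-]+$")
IDENTIFIER_COLUMNS = ("barcode", "treatment", "plate", "sample_type", "unit")

PLATE_FORMATS = {96: ("ABCDEFGH", 12), 384: ("ABCDEFGHIJKLMNOP", 24)}

_WELL_RE = re.compile(r"^([A-Za-z])0*([1-9][0-9]*)$")


class FormatError(ValueError):
    """Malformed input file (bad header, non-integer count, bad line)."""


class SchemaError(ValueError):
    """Metadata sheet violates the required-column schema."""


def canonical_well(well: str) -> str:
    """Canonicalise a well label: upper-case row letter, unpadded column.

    ``"a01"`` and ``"A1"`` both map to ``"A1"``.  Raises ``ValueError``
    for labels that do not parse at all.
    """
    m = _WELL_RE.match(str(well).strip())
    if m is None:
        raise ValueError(f"unparseable well label: {well!r}")
    return f"{m.group(1).upper()}{int(m.group(2))}"


def well_is_valid(well: str, plate_format: int = 384) -> bool:
    """True if *well* addresses a coordinate of the given plate format."""
    try:
        canon = canonical_well(well)
    except ValueError:
        return False
    rows, ncol = PLATE_FORMATS[plate_format]
    return canon[0] in rows and 1 <= int(canon[1:]) <= ncol


@dataclass
class CountMatrix:
    """Integer gene-by-well count matrix with row/column identifiers."""

    values: np.ndarray
    gene_ids: np.ndarray
    gene_names: np.ndarray
    barcodes: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("counts must be a 2-D genes x wells matrix")
        g, w = self.values.shape
        if len(self.gene_ids) != g or len(self.gene_names) != g:
            raise ValueError("gene annotation length does not match matrix rows")
        if len(self.barcodes) != w:
            raise ValueError("barcode count does not match matrix columns")
        if len(set(self.gene_ids)) != g:
            raise ValueError("gene_ids must be unique")
        if len(set(self.barcodes)) != w:
            raise ValueError("barcodes must be unique")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.all(self.values == np.floor(self.values)):
                raise FormatError("counts must be integral")
            self.values = self.values.astype(np.int64)
        if (self.values < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_wells(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, mask: np.ndarray) -> "CountMatrix":
        return CountMatrix(
            self.values[mask], self.gene_ids[mask], self.gene_names[mask], self.barcodes
        )

    def reorder_wells(self, order: Sequence[int]) -> "CountMatrix":
        order = np.asarray(order)
        return CountMatrix(
            self.values[:, order], self.gene_ids, self.gene_names, self.barcodes[order]
        )


@dataclass
class PlateMetadata:
    """Validated-on-demand sample sheet, one row per well barcode."""

    table: pd.DataFrame
    plate_format: int = 384

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.table.columns]
        if missing:
            raise SchemaError(f"metadata missing required column(s): {', '.join(missing)}")
        dup = self.table["barcode"][self.table["barcode"].duplicated()]
        if len(dup):
            raise SchemaError(f"duplicate barcode(s): {sorted(set(dup))}")
        if self.plate_format not in PLATE_FORMATS:
            raise ValueError(f"unsupported plate format: {self.plate_format}")
        self.table = self.table.reset_index(drop=True)

    @property
    def barcodes(self) -> np.ndarray:
        return self.table["barcode"].to_numpy(dtype=object)

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, mask: np.ndarray) -> "PlateMetadata":
        return PlateMetadata(self.table.loc[mask].reset_index(drop=True), self.plate_format)


@dataclass
class ValidationReport:
    """Outcome of metadata validation; ``passed`` iff no errors."""

    errors: list[tuple] = field(default_factory=list)
    warnings: list[tuple] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.errors

    def to_json(self) -> str:
        return json.dumps(
            {
                "passed": self.passed,
                "errors": [list(e) for e in self.errors],
                "warnings": [list(w) for w in self.warnings],
            },
            indent=2,
        )


@dataclass
class Screen:
    """Joined counts + metadata with an append-only provenance log."""

    counts: CountMatrix
    metadata: PlateMetadata
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.array_equal(self.counts.barcodes, self.metadata.barcodes):
            raise ValueError("count and metadata barcodes differ or are misordered")

    @property
    def n_genes(self) -> int:
        return self.counts.n_genes

    @property
    def n_wells(self) -> int:
        return self.counts.n_wells

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def with_counts(self, counts: CountMatrix, note: str) -> "Screen":
        return Screen(counts, self.metadata, self.provenance + [note])

    def wells_for(
        self,
        treatment: str | None = None,
        concentration: float | None = None,
        sample_type: str | None = None,
    ) -> np.ndarray:
        """Integer well indices matching the given metadata filters."""
        mask = np.ones(self.n_wells, dtype=bool)
        t = self.metadata.table
        if treatment is not None:
            mask &= (t["treatment"].astype(str).str.lower() == treatment.lower()).to_numpy()
        if concentration is not None:
            mask &= np.isclose(t["concentration"].to_numpy(dtype=float), concentration)
        if sample_type is not None:
            mask &= (t["sample_type"] == sample_type).to_numpy()
        return np.flatnonzero(mask)

    def vehicle_wells(self, fallback_name: str = "DMSO") -> np.ndarray:
        """Vehicle-control wells: ``sample_type == 'vehicle'`` is
        authoritative; if no well is so labelled, fall back to a
        case-insensitive treatment-name match (default ``"DMSO"``)."""
        idx = self.wells_for(sample_type="vehicle")
        if len(idx) == 0:
            idx = self.wells_for(treatment=fallback_name)
        return idx


def _open_maybe_gz(path: Path, gzipped: bool):
    if gzipped or str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def _find_triplet_file(directory: Path, stem: str, gzipped: bool) -> Path:
    exts = [".gz", ""] if gzipped else ["", ".gz"]
    for suffix in (".mtx", ".tsv", ".csv", ".txt"):
        for ext in exts:
            p = directory / f"{stem}{suffix}{ext}"
            if p.exists():
                return p
    raise FileNotFoundError(f"no {stem} file found in {directory}")


def read_count_triplet(directory: str | Path, gzipped: bool = False) -> CountMatrix:
    """Read a Cell Ranger / STARsolo style sparse triplet directory.

    Expects ``matrix.mtx`` (MatrixMarket coordinate format),
    ``features.tsv`` (2 or 3 columns: id, name[, type]) and
    ``barcodes.tsv``; any of the three may be gzipped.  Zero entries are
    implicit; the MatrixMarket dimension header is honoured.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"not a directory: {directory}")
    mtx_path = _find_triplet_file(directory, "matrix", gzipped)
    feat_path = _find_triplet_file(directory, "features", gzipped)
    bc_path = _find_triplet_file(directory, "barcodes", gzipped)

    with _open_maybe_gz(mtx_path, gzipped) as fh:
        try:
            mat = scipy.io.mmread(fh)
        except ValueError as exc:
            raise FormatError(f"{mtx_path}: {exc}") from exc
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if not np.all(dense == np.floor(dense)):
        raise FormatError(f"{mtx_path}: non-integer count value")
    dense = dense.astype(np.int64)

    with _open_maybe_gz(feat_path, gzipped) as fh:
        feats = pd.read_csv(fh, sep="\t", header=None, dtype=str)
    if feats.shape[1] == 1:
        feats[1] = feats[0]
    elif feats.shape[1] > 3:
        raise FormatError(f"{feat_path}: expected 2 or 3 columns, found {feats.shape[1]}")
    # column 3 (feature type), when present, is ignored: Cell Ranger writes
    # it, STARsolo may not.
    with _open_maybe_gz(bc_path, gzipped) as fh:
        barcodes = [line.strip().split("\t")[0] for line in fh if line.strip()]

    if dense.shape[0] != len(feats):
        raise FormatError(
            f"{mtx_path}: {dense.shape[0]} rows but {len(feats)} features listed"
        )
    if dense.shape[1] != len(barcodes):
        raise FormatError(
            f"{mtx_path}: {dense.shape[1]} columns but {len(barcodes)} barcodes listed"
        )
    return CountMatrix(
        dense,
        feats[0].to_numpy(dtype=object),
        feats[1].to_numpy(dtype=object),
        np.asarray(barcodes, dtype=object),
    )


def write_count_triplet(
    counts: CountMatrix, directory: str | Path, gzipped: bool = False
) -> None:
    """Write the triplet layout read back by :func:`read_count_triplet`."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ext = ".gz" if gzipped else ""

    sparse = scipy.sparse.coo_matrix(counts.values)
    mtx_path = directory / f"matrix.mtx{ext}"
    if gzipped:
        with gzip.open(mtx_path, "wb") as fh:
            scipy.io.mmwrite(fh, sparse, field="integer")
    else:
        scipy.io.mmwrite(str(mtx_path), sparse, field="integer")

    feats = pd.DataFrame(
        {"id": counts.gene_ids, "name": counts.gene_names, "type": "Gene Expression"}
    )
    feats.to_csv(directory / f"features.tsv{ext}", sep="\t", header=False, index=False)
    pd.Series(counts.barcodes).to_csv(
        directory / f"barcodes.tsv{ext}", sep="\t", header=False, index=False
    )


def read_metadata(
    path: str | Path,
    dialect: str = "tsv",
    synonyms: Mapping[str, str] | None = None,
    plate_format: int = 384,
) -> PlateMetadata:
    """Read a delimited sample sheet, mapping headers case-insensitively.

    Required columns may appear under any name listed in the synonym table
    (:data:`DEFAULT_SYNONYMS` plus the caller's *synonyms*, which win).
    Extra columns are preserved verbatim.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"metadata file not found: {path}")
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    table = pd.read_csv(path, sep=sep, dtype={"barcode": str})

    mapping = {k.lower(): v for k, v in DEFAULT_SYNONYMS.items()}
    mapping.update({c.lower(): c for c in REQUIRED_COLUMNS})
    if synonyms:
        mapping.update({k.lower(): v for k, v in synonyms.items()})
    rename = {}
    for col in table.columns:
        target = mapping.get(col.strip().lower())
        if target is not None and target not in rename.values():
            rename[col] = target
    table = table.rename(columns=rename)

    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"metadata missing required column(s): {', '.join(missing)}")
    table["barcode"] = table["barcode"].astype(str)
    return PlateMetadata(table, plate_format=plate_format)


def write_metadata(meta: PlateMetadata, path: str | Path, dialect: str = "tsv") -> None:
    sep = {"csv": ",", "tsv": "\t"}[dialect]
    meta.table.to_csv(path, sep=sep, index=False)


def validate_metadata(
    meta: PlateMetadata,
    identifier_columns: Iterable[str] = IDENTIFIER_COLUMNS,
) -> ValidationReport:
    """Run the automated sheet checks and return a report (never raises).

    Errors: missing values in required columns, characters outside
    ``[A-Za-z0-9._-]`` in identifier columns, invalid well coordinates for
    the declared plate format, negative concentrations, duplicated
    (plate, well) pairs.  Warnings: single-replicate treatment groups and
    unbalanced replicate counts.
    """
    report = ValidationReport()
    t = meta.table

    for col in REQUIRED_COLUMNS:
        null = t[col].isna() | (t[col].astype(str).str.strip() == "")
        for row in np.flatnonzero(null.to_numpy()):
            report.errors.append((int(row), col, "missing_value", f"missing value in {col!r}"))

    for col in identifier_columns:
        if col not in t.columns:
            continue
        for row, value in enumerate(t[col].astype(str)):
            if value and not IDENTIFIER_PATTERN.match(value):
                bad = sorted({c for c in value if not IDENTIFIER_PATTERN.match(c)})
                report.errors.append(
                    (row, col, "special_characters",
                     f"{value!r} contains disallowed character(s): {bad}")
                )

    for row, well in enumerate(t["well"].astype(str)):
        if not well_is_valid(well, meta.plate_format):
            report.errors.append(
                (row, "well", "invalid_well",
                 f"{well!r} is not a valid {meta.plate_format}-well coordinate")
            )

    conc = pd.to_numeric(t["concentration"], errors="coerce")
    for row in np.flatnonzero((conc < 0).to_numpy()):
        report.errors.append(
            (int(row), "concentration", "negative_concentration",
             f"negative concentration {conc.iloc[row]}")
        )

    try:
        wells_canon = t["well"].astype(str).map(canonical_well)
        pw = list(zip(t["plate"].astype(str), wells_canon))
        seen: dict[tuple, int] = {}
        for row, key in enumerate(pw):
            if key in seen:
                report.errors.append(
                    (row, "well", "duplicate_plate_well",
                     f"(plate, well) {key} already used in row {seen[key]}")
                )
            else:
                seen[key] = row
    except ValueError:
        pass  # unparseable wells already reported above

    treated = t[t["sample_type"] == "treatment"]
    if len(treated):
        sizes = treated.groupby(["treatment", "concentration"], dropna=False).size()
        for key, n in sizes.items():
            if n == 1:
                report.warnings.append(
                    (-1, "replicate", "single_replicate",
                     f"treatment group {key} has a single replicate")
                )
        if sizes.nunique() > 1:
            report.warnings.append(
                (-1, "replicate", "unbalanced_replicates",
                 f"replicate counts vary across groups: {sorted(set(sizes))}")
            )
    return report


def assemble_screen(
    counts: CountMatrix, meta: PlateMetadata, drop_unmatched: bool = False
) -> Screen:
    """Join counts and metadata on barcode, reordering counts to sheet order.

    With ``drop_unmatched`` barcodes present on only one side are removed
    (logged); otherwise any mismatch is an error.  An empty barcode
    intersection is always an error.
    """
    count_bc = list(counts.barcodes)
    meta_bc = list(meta.barcodes)
    inter = set(count_bc) & set(meta_bc)
    if not inter:
        raise ValueError("no barcodes shared between counts and metadata")

    provenance: list[str] = []
    only_counts = [b for b in count_bc if b not in inter]
    only_meta = [b for b in meta_bc if b not in inter]
    if only_counts or only_meta:
        if not drop_unmatched:
            raise ValueError(
                f"barcode mismatch: {len(only_counts)} only in counts, "
                f"{len(only_meta)} only in metadata (use drop_unmatched to keep the intersection)"
            )
        provenance.append(
            f"warning: dropped unmatched barcodes "
            f"(counts-only: {len(only_counts)}, metadata-only: {len(only_meta)})"
        )
        meta = meta.subset(np.asarray([b in inter for b in meta_bc]))

    pos = {b: i for i, b in enumerate(count_bc)}
    order = [pos[b] for b in meta.barcodes]
    provenance.insert(0, f"assembled screen: {counts.n_genes} genes x {len(order)} wells")
    return Screen(counts.reorder_wells(order), meta, provenance)
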