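"""Reading, writing and normalising expression profile matrices.

The central container is :class:`ExpressionMatrix`, a genes x samples matrix
of robust z-scores (a sample's expression standardised against the median and
median absolute deviation of the vehicle-control wells on its plate).
Supported on-disk formats are GCT (text, dialects ``#1.2`` and ``#1.3``),
GCTX (HDF5) and plain delimited tables; sample metadata, compound annotations
and GMT gene-set files round out the interfaces the rest of the package
consumes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleMetadata",
    "CompoundAnnotation",
    "FormatError",
    "ValidationError",
    "read_expression",
    "write_expression",
    "compute_robust_zscores",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "write_annotations",
    "read_gmt",
    "write_gmt",
    "N_LANDMARK_GENES",
]

#: Number of directly measured landmark genes on the L1000 platform.
N_LANDMARK_GENES = 978

#: Consistency constant making the MAD an unbiased scale estimate under
#: normality (1 / Phi^-1(3/4)).
MAD_CONSISTENCY = 1.4826


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class ValidationError(ValueError):
    """A container violates one of its invariants."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of (robust z-score) expression values.

    Invariants: identifiers are unique, values are finite, and the value
    matrix shape matches the identifier lists.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 2:
            raise ValidationError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValidationError("duplicate sample identifiers")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("values contain non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, idx])


@dataclass
class SampleMetadata:
    """Per-sample treatment record.

    Samples sharing a ``replicate_group_id`` are biological replicates:
    identical compound, cell line and dose, treated and lysed on separate
    days (hence typically in different plate batches).
    """

    sample_id: str
    compound_id: str
    replicate_group_id: str
    batch_id: str
    cell_line: str
    dose: float | None = None
    is_vehicle: bool = False


@dataclass
class CompoundAnnotation:
    """External knowledge about one compound.

    ``targets`` lists (target_id, potency in uM) records; only sub-micromolar
    potencies are considered "annotated" downstream.  ``hts_fingerprint`` is
    the compound's vector of activity z-scores across high-throughput screens
    (clipped to [-20, 20] so artifactual values do not dominate correlations);
    ``promiscuity`` is the fraction of those screens calling the compound a
    hit.
    """

    compound_id: str
    targets: list[tuple[str, float]] = field(default_factory=list)
    structure_cluster_id: str | None = None
    hts_fingerprint: np.ndarray | None = None
    promiscuity: float | None = None

    def __post_init__(self) -> None:
        for target_id, potency in self.targets:
            if potency <= 0:
                raise ValidationError(
                    f"non-positive potency {potency} for target {target_id!r} "
                    f"of compound {self.compound_id!r}"
                )
        if self.promiscuity is not None and not 0.0 <= self.promiscuity <= 1.0:
            raise ValidationError(
                f"promiscuity {self.promiscuity} outside [0, 1] for {self.compound_id!r}"
            )
        if self.hts_fingerprint is not None:
            fp = np.asarray(self.hts_fingerprint, dtype=float)
            self.hts_fingerprint = np.clip(fp, -20.0, 20.0)

    def sub_micromolar_targets(self, cutoff: float = 1.0) -> list[str]:
        return [t for t, potency in self.targets if potency < cutoff]


# ---------------------------------------------------------------------------
# Expression matrix formats
# ---------------------------------------------------------------------------


def read_expression(path: str, format: str | None = None,
                    landmark_only: bool = False) -> ExpressionMatrix:
    """Read an expression matrix from GCT, GCTX or a delimited table.

    With ``landmark_only`` the first :data:`N_LANDMARK_GENES` rows are
    retained in file order (the directly measured genes come first in L1000
    matrices; the remainder are computationally inferred).
    """
    if format is None:
        format = _guess_format(path)
    if format == "gct":
        matrix = _read_gct(path)
    elif format == "gctx":
        matrix = _read_gctx(path)
    elif format == "delimited":
        matrix = _read_delimited(path)
    else:
        raise ValueError(f"unknown format {format!r}")
    if landmark_only:
        n = min(N_LANDMARK_GENES, matrix.n_genes)
        matrix = ExpressionMatrix(matrix.gene_ids[:n], matrix.sample_ids,
                                  matrix.values[:n])
    return matrix


def write_expression(matrix: ExpressionMatrix, path: str,
                     format: str | None = None) -> None:
    """Write a matrix readable back by :func:`read_expression`.

    GCT output uses the ``#1.3`` dialect with row/column counts on line 2.
    """
    matrix.validate()
    if format is None:
        format = _guess_format(path)
    if format == "gct":
        _write_gct(matrix, path)
    elif format == "gctx":
        _write_gctx(matrix, path)
    elif format == "delimited":
        matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    else:
        raise ValueError(f"unknown format {format!r}")


def _guess_format(path: str) -> str:
    lower = path.lower()
    if lower.endswith(".gctx"):
        return "gctx"
    if lower.endswith(".gct"):
        return "gct"
    return "delimited"


def _read_gct(path: str) -> ExpressionMatrix:
    with open(path) as fh:
        version = fh.readline().strip()
        if version not in ("#1.2", "#1.3"):
            raise FormatError(f"unsupported GCT version line: {version!r}")
        dims_line = fh.readline().strip()
        fields = dims_line.split("\t")
        try:
            dims = [int(f) for f in fields]
        except ValueError:
            raise FormatError(f"malformed GCT dimension line: {dims_line!r}") from None
        if version == "#1.2":
            if len(dims) != 2:
                raise FormatError(f"malformed GCT dimension line: {dims_line!r}")
            n_rows, n_cols = dims
            n_row_meta = 1  # the fixed Description column
            n_col_meta = 0
        else:
            if len(dims) != 4:
                raise FormatError(f"malformed GCT dimension line: {dims_line!r}")
            n_rows, n_cols, n_row_meta, n_col_meta = dims
        header = fh.readline().rstrip("\n").split("\t")
        expected_width = 1 + n_row_meta + n_cols
        if len(header) != expected_width:
            raise FormatError(
                f"malformed GCT header (expected {expected_width} fields, "
                f"got {len(header)}): {header!r}"
            )
        sample_ids = header[1 + n_row_meta:]
        for _ in range(n_col_meta):  # column-metadata rows precede the data
            fh.readline()
        gene_ids: list[str] = []
        rows = np.empty((n_rows, n_cols), dtype=float)
        for i in range(n_rows):
            line = fh.readline()
            if not line:
                raise FormatError(f"truncated GCT: expected {n_rows} data rows, got {i}")
            parts = line.rstrip("\n").split("\t")
            if len(parts) != expected_width:
                raise FormatError(f"malformed GCT data row {i + 1}: {line!r}")
            gene_ids.append(parts[0])
            try:
                rows[i] = [float(v) for v in parts[1 + n_row_meta:]]
            except ValueError:
                raise FormatError(f"non-numeric value in GCT data row {i + 1}") from None
    return ExpressionMatrix(gene_ids, sample_ids, rows)


def _write_gct(matrix: ExpressionMatrix, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("#1.3\n")
        fh.write(f"{matrix.n_genes}\t{matrix.n_samples}\t0\t0\n")
        fh.write("id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gene + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def _read_gctx(path: str) -> ExpressionMatrix:
    with h5py.File(path, "r") as fh:
        data = fh["0/DATA/0/matrix"][()]
        gene_ids = [_decode(v) for v in fh["0/META/ROW/id"][()]]
        sample_ids = [_decode(v) for v in fh["0/META/COL/id"][()]]
    # GCTX stores the matrix samples x genes
    return ExpressionMatrix(gene_ids, sample_ids, np.asarray(data, dtype=float).T)


def _write_gctx(matrix: ExpressionMatrix, path: str) -> None:
    with h5py.File(path, "w") as fh:
        fh.attrs["version"] = "GCTX1.0"
        fh.create_dataset("0/DATA/0/matrix", data=matrix.values.T)
        str_dt = h5py.string_dtype("utf-8")
        fh.create_dataset("0/META/ROW/id", data=matrix.gene_ids, dtype=str_dt)
        fh.create_dataset("0/META/COL/id", data=matrix.sample_ids, dtype=str_dt)


def _decode(value) -> str:
    return value.decode() if isinstance(value, bytes) else str(value)


def _read_delimited(path: str) -> ExpressionMatrix:
    sep = "," if path.lower().endswith(".csv") else "\t"
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix([str(g) for g in frame.index],
                            [str(s) for s in frame.columns],
                            frame.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Robust z-scoring
# ---------------------------------------------------------------------------


def compute_robust_zscores(plate_values: np.ndarray,
                           vehicle_wells,
                           gene_ids: list[str] | None = None,
                           sample_ids: list[str] | None = None,
                           consistency: bool = True) -> ExpressionMatrix:
    """Standardise a plate of normalised intensities against vehicle controls.

    For each gene g and well s,

        z[g, s] = (x[g, s] - median_vehicle[g]) / (MAD_vehicle[g] * k)

    where the median and MAD are taken over the vehicle (DMSO) control wells
    of the plate and ``k = 1.4826`` when ``consistency`` is set (default; the
    constant makes the MAD estimate the standard deviation under normality),
    else 1.  A gene whose vehicle MAD is zero is an error — silent epsilon
    inflation would fabricate huge z-scores.
    """
    plate_values = np.asarray(plate_values, dtype=float)
    if plate_values.ndim != 2:
        raise ValueError("plate_values must be genes x wells")
    n_genes, n_wells = plate_values.shape
    vehicle_wells = np.asarray(list(vehicle_wells), dtype=int)
    if vehicle_wells.size < 2:
        raise ValueError("need at least 2 vehicle wells to estimate location/scale")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if sample_ids is None:
        sample_ids = [f"s{j}" for j in range(n_wells)]
    vehicle = plate_values[:, vehicle_wells]
    med = np.median(vehicle, axis=1)
    mad = np.median(np.abs(vehicle - med[:, None]), axis=1)
    zero = np.flatnonzero(mad == 0)
    if zero.size:
        raise ValueError(
            "vehicle MAD is zero for gene(s): "
            + ", ".join(gene_ids[i] for i in zero[:10])
        )
    scale = mad * (MAD_CONSISTENCY if consistency else 1.0)
    z = (plate_values - med[:, None]) / scale[:, None]
    return ExpressionMatrix(list(gene_ids), list(sample_ids), z)


# ---------------------------------------------------------------------------
# Metadata / annotation tables
# ---------------------------------------------------------------------------

_METADATA_COLUMNS = ["sample_id", "compound_id", "replicate_group_id",
                     "batch_id", "cell_line", "dose", "is_vehicle"]


def write_metadata(records: list[SampleMetadata], path: str) -> None:
    frame = pd.DataFrame(
        [(r.sample_id, r.compound_id, r.replicate_group_id, r.batch_id,
          r.cell_line, r.dose, int(r.is_vehicle)) for r in records],
        columns=_METADATA_COLUMNS,
    )
    frame.to_csv(path, sep="\t", index=False)


def read_metadata(path: str) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype={c: str for c in _METADATA_COLUMNS[:5]})
    missing = set(_METADATA_COLUMNS) - set(frame.columns)
    if missing:
        raise FormatError(f"metadata table missing columns: {sorted(missing)}")
    records = []
    for row in frame.itertuples(index=False):
        dose = None if pd.isna(row.dose) else float(row.dose)
        records.append(SampleMetadata(row.sample_id, row.compound_id,
                                      row.replicate_group_id, row.batch_id,
                                      row.cell_line, dose, bool(int(row.is_vehicle))))
    return records


def write_annotations(annotations: list[CompoundAnnotation], path: str,
                      fingerprint_path: str | None = None) -> None:
    """Write compound annotations as TSV; fingerprints go to a separate
    compounds x assays table because they are a dense matrix."""
    rows = []
    for a in annotations:
        targets = ";".join(f"{t}:{p:g}" for t, p in a.targets)
        rows.append((a.compound_id, targets, a.structure_cluster_id or "",
                     "" if a.promiscuity is None else a.promiscuity))
    pd.DataFrame(rows, columns=["compound_id", "targets", "structure_cluster_id",
                                "promiscuity"]).to_csv(path, sep="\t", index=False)
    if fingerprint_path is not None:
        with_fp = [a for a in annotations if a.hts_fingerprint is not None]
        if with_fp:
            n_assays = len(with_fp[0].hts_fingerprint)
            frame = pd.DataFrame(
                np.vstack([a.hts_fingerprint for a in with_fp]),
                index=[a.compound_id for a in with_fp],
                columns=[f"assay_{j}" for j in range(n_assays)],
            )
            frame.to_csv(fingerprint_path, sep="\t", index_label="compound_id")


def read_annotations(path: str,
                     fingerprint_path: str | None = None) -> list[CompoundAnnotation]:
    frame = pd.read_csv(path, sep="\t", dtype={"compound_id": str,
                                               "structure_cluster_id": str})
    fingerprints: dict[str, np.ndarray] = {}
    if fingerprint_path is not None and os.path.exists(fingerprint_path):
        fp_frame = pd.read_csv(fingerprint_path, sep="\t", index_col=0)
        fingerprints = {str(c): fp_frame.loc[c].to_numpy(dtype=float)
                        for c in fp_frame.index}
    annotations = []
    for row in frame.itertuples(index=False):
        targets = []
        if isinstance(row.targets, str) and row.targets:
            for item in row.targets.split(";"):
                target_id, potency = item.rsplit(":", 1)
                targets.append((target_id, float(potency)))
        cluster = row.structure_cluster_id if isinstance(row.structure_cluster_id, str) else None
        promiscuity = None if pd.isna(row.promiscuity) else float(row.promiscuity)
        annotations.append(CompoundAnnotation(
            row.compound_id, targets, cluster or None,
            fingerprints.get(row.compound_id), promiscuity))
    return annotations


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str) -> dict[str, list[str]]:
    """Read a GMT file: one set per line, ``name<TAB>description<TAB>genes...``."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"malformed GMT line {lineno}: {line!r}")
            name, genes = parts[0], [g for g in parts[2:] if g]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            if not genes:
                raise ValidationError(f"empty gene set {name!r}")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path: str) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write(name + "\tna\t" + "\t".join(genes) + "\n")
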