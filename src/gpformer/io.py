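"""Genotype, phenotype and marker-map I/O, QC filters and numeric encodings.

Genotype calls are stored as small-integer dosage codes: ``0`` = homozygous
reference (0/0), ``1`` = heterozygous (0/1), ``2`` = homozygous alternate
(1/1) and :data:`MISSING` (= -1) for an uncalled genotype.  Missingness is
explicit; mode imputation must be applied before additive encoding so that
the weighted one-hot path can still observe missing calls as (0,0,0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for an uncalled genotype, distinct from the legal dosage codes.
MISSING: int = -1


class GenotypeFormatError(ValueError):
    """Raised when a genotype file cannot be parsed under its declared format."""


class AlignmentError(ValueError):
    """Raised when sample or marker identifiers of two containers disagree."""


@dataclass
class GenotypeMatrix:
    """n samples x p biallelic markers with per-marker genomic coordinates.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, one per row of ``calls``.
    markers : list of str
        Marker identifiers, one per column of ``calls``.
    calls : ndarray of int, shape (n_samples, n_markers)
        Dosage codes in {0, 1, 2, MISSING}.
    chrom : ndarray of str, shape (n_markers,)
        Chromosome label per marker.
    pos : ndarray of int, shape (n_markers,)
        Physical position in base pairs; non-decreasing within a chromosome.
    """

    samples: list[str]
    markers: list[str]
    calls: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int16)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        n, p = self.calls.shape
        if n != len(self.samples) or p != len(self.markers):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        if self.chrom.shape != (p,) or self.pos.shape != (p,):
            raise ValueError("chrom/pos must have one entry per marker")
        if np.any(self.pos < 0):
            raise ValueError("physical positions must be non-negative")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"illegal call code {self.calls[i, j]} at sample "
                f"{self.samples[i]!r}, marker {self.markers[j]!r}"
            )
        for c in pd.unique(self.chrom):
            pc = self.pos[self.chrom == c]
            if np.any(np.diff(pc) < 0):
                raise ValueError(f"positions not sorted within chromosome {c!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency over non-missing calls.

        Markers with no observed calls get NaN.  Invariant to allele-label
        swap: min(f, 1-f) of the alternate-allele frequency.
        """
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            alt = np.where(obs, self.calls, 0).sum(axis=0) / (2.0 * n_obs)
        f = np.where(n_obs > 0, alt, np.nan)
        return np.minimum(f, 1.0 - f)

    def missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def subset_markers(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        cols = np.flatnonzero(index) if index.dtype == bool else index
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[i] for i in cols],
            calls=self.calls[:, cols],
            chrom=self.chrom[cols],
            pos=self.pos[cols],
        )

    def subset_samples(self, index: np.ndarray) -> "GenotypeMatrix":
        index = np.asarray(index)
        rows = np.flatnonzero(index) if index.dtype == bool else index
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            markers=list(self.markers),
            calls=self.calls[rows, :],
            chrom=self.chrom,
            pos=self.pos,
        )


@dataclass
class PhenotypeVector:
    """One quantitative trait aligned to a :class:`GenotypeMatrix`."""

    samples: list[str]
    values: np.ndarray
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.samples),):
            raise ValueError("one phenotype value per sample required")

    def subset(self, index: np.ndarray) -> "PhenotypeVector":
        index = np.asarray(index)
        rows = np.flatnonzero(index) if index.dtype == bool else index
        return PhenotypeVector(
            samples=[self.samples[i] for i in rows],
            values=self.values[rows],
            trait_name=self.trait_name,
        )


@dataclass
class EncodedInput:
    """Numeric network input: n samples x C channels x L markers."""

    array: np.ndarray
    encoding_kind: str

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=np.float64)
        if self.array.ndim != 3:
            raise ValueError("encoded input must be (n, channels, markers)")

    @property
    def n_channels(self) -> int:
        return self.array.shape[1]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _map_path_for(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".map")


def read_genotypes(
    path: str | Path,
    format: str | None = None,
    map_path: str | Path | None = None,
    on_multiallelic: str = "error",
) -> GenotypeMatrix:
    """Read a genotype matrix from VCF or the package's CSV dialect.

    The CSV dialect is: header row ``sample,<marker ids...>``, one row per
    sample, cells in {0,1,2} or ``NA`` for missing, with a side-car
    tab-separated map file (``marker  chrom  pos``) found at
    ``<path>.map`` unless ``map_path`` is given.

    Parameters
    ----------
    on_multiallelic : {"error", "drop"}
        VCF sites with more than one ALT allele either raise a
        :class:`GenotypeFormatError` or are silently dropped.
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "csv"
    if format == "vcf":
        return _read_vcf(path, on_multiallelic=on_multiallelic)
    if format == "csv":
        return _read_csv(path, map_path=map_path)
    raise ValueError(f"unknown genotype format {format!r}")


def _read_vcf(path: Path, on_multiallelic: str = "error") -> GenotypeMatrix:
    from cyvcf2 import VCF

    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, chrom, pos, rows = [], [], [], []
    # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
    code = np.array([0, 1, MISSING, 2], dtype=np.int16)
    for i, var in enumerate(vcf):
        if len(var.ALT) != 1:
            if on_multiallelic == "drop":
                continue
            raise GenotypeFormatError(
                f"non-biallelic site {var.CHROM}:{var.POS} (record {i + 1}); "
                "pass on_multiallelic='drop' to skip such sites"
            )
        markers.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)  # 1-based, stored unchanged
        rows.append(code[var.gt_types])
    calls = (
        np.stack(rows, axis=1) if rows else np.empty((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(samples, markers, calls, np.array(chrom, dtype=object), np.array(pos))


def _read_csv(path: Path, map_path: str | Path | None = None) -> GenotypeMatrix:
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, index_col=0, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise GenotypeFormatError(f"cannot parse {path}: {exc}") from exc
    calls = np.full(df.shape, MISSING, dtype=np.int16)
    vals = df.to_numpy()
    for code in (0, 1, 2):
        calls[vals == str(code)] = code
    unknown = ~np.isin(vals, [str(c) for c in (0, 1, 2)]) & ~pd.isna(vals) & (vals != "NA")
    if unknown.any():
        i, j = np.argwhere(unknown)[0]
        raise GenotypeFormatError(
            f"{path}, line {i + 2}: illegal genotype cell {vals[i, j]!r} "
            f"(expected 0/1/2/NA)"
        )
    map_path = Path(map_path) if map_path is not None else _map_path_for(path)
    if not map_path.exists():
        raise GenotypeFormatError(f"marker map not found at {map_path}")
    m = pd.read_csv(map_path, sep="\t", dtype={"marker": str, "chrom": str, "pos": np.int64})
    if not {"marker", "chrom", "pos"}.issubset(m.columns):
        raise GenotypeFormatError(
            f"map file {map_path} must have columns marker/chrom/pos, found {list(m.columns)}"
        )
    m = m.set_index("marker").reindex(df.columns)
    if m["pos"].isna().any():
        missing = m.index[m["pos"].isna()][0]
        raise GenotypeFormatError(f"marker {missing!r} absent from map file {map_path}")
    return GenotypeMatrix(
        samples=[str(s) for s in df.index],
        markers=[str(c) for c in df.columns],
        calls=calls,
        chrom=m["chrom"].to_numpy(dtype=object),
        pos=m["pos"].to_numpy(dtype=np.int64),
    )


def write_genotypes(g: GenotypeMatrix, path: str | Path, map_path: str | Path | None = None) -> None:
    """Write the CSV genotype matrix and its side-car marker map."""
    path = Path(path)
    cells = g.calls.astype(object)
    cells[g.calls == MISSING] = "NA"
    pd.DataFrame(cells, index=g.samples, columns=g.markers).to_csv(path, index_label="sample")
    map_path = Path(map_path) if map_path is not None else _map_path_for(path)
    pd.DataFrame({"marker": g.markers, "chrom": g.chrom, "pos": g.pos}).to_csv(
        map_path, sep="\t", index=False
    )


def read_phenotypes(path: str | Path, trait: str | None = None) -> PhenotypeVector:
    """Read one trait from a TSV phenotype table (``sample`` + trait columns)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str}).set_index("sample")
    if trait is None:
        trait = df.columns[0]
    if trait not in df.columns:
        raise KeyError(f"trait {trait!r} not in {list(df.columns)}")
    return PhenotypeVector(list(df.index), df[trait].to_numpy(np.float64), trait)


def write_phenotypes(y: PhenotypeVector, path: str | Path) -> None:
    pd.DataFrame({"sample": y.samples, y.trait_name: y.values}).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# QC and imputation
# ---------------------------------------------------------------------------

def qc_filter(g: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.1) -> GenotypeMatrix:
    """Drop markers with MAF < ``maf_min`` or missing rate > ``miss_max``.

    The standard pre-training marker QC: minor allele frequency is computed
    on non-missing calls only, and an all-missing marker is removed with a
    warning rather than dividing by zero.  Samples are never removed.
    Idempotent: a second application with the same thresholds is a no-op.
    """
    if not 0.0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0.0 <= miss_max <= 1.0:
        raise ValueError("miss_max must be in [0, 1]")
    maf = g.maf()
    miss = g.missing_rate()
    all_missing = np.isnan(maf)
    if all_missing.any():
        warnings.warn(
            f"removing {int(all_missing.sum())} marker(s) with no observed calls",
            stacklevel=2,
        )
    keep = ~all_missing & (maf >= maf_min) & (miss <= miss_max)
    return g.subset_markers(keep)


def impute_mode(g: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing calls with the marker's most frequent observed code.

    Ties break toward the smaller code.  A stand-in for nearest-neighbour
    imputation: adequate for the low missing rates left after QC.
    """
    calls = g.calls.copy()
    for j in np.flatnonzero(g.missing_mask().any(axis=0)):
        col = calls[:, j]
        obs = col[col != MISSING]
        if obs.size == 0:
            raise ValueError(
                f"marker {g.markers[j]!r} is entirely missing; run qc_filter first"
            )
        mode = int(np.bincount(obs, minlength=3).argmax())  # argmax -> smallest code on tie
        col[col == MISSING] = mode
    return GenotypeMatrix(list(g.samples), list(g.markers), calls, g.chrom, g.pos)


# ---------------------------------------------------------------------------
# encodings
# ---------------------------------------------------------------------------

def encode_additive(g: GenotypeMatrix) -> EncodedInput:
    """Single-channel dosage encoding (0/1/2); requires a fully imputed matrix."""
    if g.missing_mask().any():
        raise ValueError("additive encoding requires an imputed matrix (run impute_mode)")
    return EncodedInput(g.calls[:, None, :].astype(np.float64), "additive")


def encode_onehot(g: GenotypeMatrix) -> EncodedInput:
    """Three-channel one-hot encoding; a missing call maps to (0, 0, 0)."""
    arr = np.zeros((g.n_samples, 3, g.n_markers), dtype=np.float64)
    for code in (0, 1, 2):
        arr[:, code, :] = g.calls == code
    return EncodedInput(arr, "onehot")


def decode_onehot(x: EncodedInput) -> np.ndarray:
    """Invert :func:`encode_onehot`: argmax per marker, (0,0,0) -> MISSING."""
    hot = x.array > 0
    calls = np.where(hot.any(axis=1), x.array.argmax(axis=1), MISSING)
    return calls.astype(np.int16)
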