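"""Single-marker association scans and GWAS-guided marker weighting.

The knowledge-guided encoding treats association evidence as an attention
prior: each marker's one-hot channels are scaled by

    w = -log10(P) + F        (numeric P),    w = 1 otherwise,

so markers with strong genotype-phenotype association dominate the weighted
channels while markers never tested keep unit weight.  Association results
can come from the built-in general-linear-model scan or from an external
TASSEL-style statistics table.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import (
    AlignmentError,
    EncodedInput,
    GenotypeMatrix,
    GenotypeFormatError,
    PhenotypeVector,
    encode_onehot,
)


@dataclass
class GwasResult:
    """Per-marker F statistics and p-values aligned to a genotype matrix.

    Untestable markers (e.g. monomorphic) carry NaN in both columns.
    """

    markers: list[str]
    f_values: np.ndarray
    p_values: np.ndarray

    def __post_init__(self) -> None:
        self.f_values = np.asarray(self.f_values, dtype=np.float64)
        self.p_values = np.asarray(self.p_values, dtype=np.float64)
        p = len(self.markers)
        if self.f_values.shape != (p,) or self.p_values.shape != (p,):
            raise ValueError("one F and one p per marker required")
        if np.any(~np.isnan(self.p_values) & np.isnan(self.f_values)):
            raise ValueError("numeric p-value with non-numeric F is inconsistent")

    def align_to(self, g: GenotypeMatrix) -> "GwasResult":
        """Reorder by marker id to match ``g``; unknown markers get NaN."""
        idx = {m: i for i, m in enumerate(self.markers)}
        f = np.full(g.n_markers, np.nan)
        p = np.full(g.n_markers, np.nan)
        for j, m in enumerate(g.markers):
            if m in idx:
                f[j] = self.f_values[idx[m]]
                p[j] = self.p_values[idx[m]]
        return GwasResult(list(g.markers), f, p)


@dataclass
class WeightVector:
    """Non-negative per-marker attention weights derived from GWAS evidence."""

    markers: list[str]
    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=np.float64)
        if self.w.shape != (len(self.markers),):
            raise ValueError("one weight per marker required")
        if np.any(self.w < 0) or not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite and non-negative")


def glm_association(g: GenotypeMatrix, y: PhenotypeVector) -> GwasResult:
    """Single-marker GLM scan: F-test of y on additive dosage, df (1, n-2).

    Vectorized simple linear regression per marker.  Equivalent to fitting
    an ordinary least-squares model per marker and testing the slope; the
    test suite cross-checks against statsmodels OLS.  Monomorphic markers
    get NaN F and p.  No structure correction (no kinship/PCs) — this is
    the plain general-linear-model scan.
    """
    if g.samples != y.samples:
        raise AlignmentError("sample ids of genotypes and phenotype differ")
    if g.missing_mask().any():
        raise ValueError("association scan requires an imputed matrix")
    yv = y.values
    if not np.all(np.isfinite(yv)):
        raise ValueError("phenotype contains non-finite values")
    n = g.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for an F test with df (1, n-2)")
    x = g.calls.astype(np.float64)
    xc = x - x.mean(axis=0)
    yc = yv - yv.mean()
    sxx = (xc**2).sum(axis=0)
    syy = float((yc**2).sum())
    if syy == 0.0:
        raise ValueError("phenotype has zero variance")
    sxy = xc.T @ yc
    f = np.full(g.n_markers, np.nan)
    p = np.full(g.n_markers, np.nan)
    ok = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = (sxy[ok] ** 2) / (sxx[ok] * syy)
        r2 = np.clip(r2, 0.0, 1.0)
        df2 = n - 2
        fo = df2 * r2 / (1.0 - r2)  # inf at exact fit is legitimate
    f[ok] = fo
    p[ok] = stats.f.sf(fo, 1, df2)
    return GwasResult(list(g.markers), f, p)


_MARKER_COLS = ("Marker", "marker", "SNP", "snp", "rs")
_F_COLS = ("F", "f", "marker_F", "marker_f")
_P_COLS = ("p", "P", "marker_p", "p_value", "P-value", "Pr(>F)")


def read_tassel_stats(path: str | Path, g: GenotypeMatrix | None = None) -> GwasResult:
    """Parse a TASSEL-style tab-separated association statistics table.

    Requires a marker column plus F and p columns (GLM/MLM "stats" dialect);
    "NaN" or empty cells become non-numeric.  When ``g`` is given the result
    is re-aligned to its marker order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)

    def pick(cands: tuple[str, ...]) -> str:
        for c in cands:
            if c in df.columns:
                return c
        raise GenotypeFormatError(
            f"{path}: none of {cands} among columns {list(df.columns)}"
        )

    mcol, fcol, pcol = pick(_MARKER_COLS), pick(_F_COLS), pick(_P_COLS)
    f = pd.to_numeric(df[fcol], errors="coerce").to_numpy(np.float64)
    p = pd.to_numeric(df[pcol], errors="coerce").to_numpy(np.float64)
    f = np.where(np.isfinite(p) & ~np.isfinite(f), np.nan, f)
    p = np.where(~np.isfinite(f), np.nan, p)
    res = GwasResult(list(df[mcol].astype(str)), f, p)
    return res.align_to(g) if g is not None else res


def compute_weights(
    r: GwasResult, p_floor: float = 1e-20, log_base: float = 10.0
) -> WeightVector:
    """Attention weight per marker: w = -log(P) + F for numeric P, else 1.

    ``p_floor`` caps the contribution of numerically-zero p-values; the
    logarithm base defaults to 10, the GWAS "negative log P" convention.
    """
    finite_f = r.f_values[np.isfinite(r.f_values)]
    if np.any(finite_f < 0):
        raise ValueError("F statistics must be non-negative")
    numeric = np.isfinite(r.p_values)
    p = np.where(numeric, np.maximum(r.p_values, p_floor), 1.0)
    f = np.where(numeric, r.f_values, 0.0)
    w = np.where(numeric, -np.log(p) / np.log(log_base) + f, 1.0)
    return WeightVector(list(r.markers), w)


def kgm_encode(g: GenotypeMatrix, w: WeightVector) -> EncodedInput:
    """Weighted one-hot encoding: the Hadamard product of the one-hot
    channels with the per-marker weight, i.e. 0/0 -> (w,0,0), 0/1 -> (0,w,0),
    1/1 -> (0,0,w) and missing -> (0,0,0)."""
    if w.markers != g.markers:
        raise AlignmentError("weight vector markers do not match genotype markers")
    base = encode_onehot(g)
    return EncodedInput(base.array * w.w[None, None, :], "kgm")


def build_model_input(
    g: GenotypeMatrix, base_encoding: str = "additive", weights: WeightVector | None = None
) -> EncodedInput:
    """Assemble the network input: base channels, plus KGM channels when
    ``weights`` is given (concatenated along the channel axis)."""
    from .io import encode_additive  # local import avoids cycle at module load

    if base_encoding == "additive":
        base = encode_additive(g)
    elif base_encoding == "onehot":
        base = encode_onehot(g)
    else:
        raise ValueError("base_encoding must be 'additive' or 'onehot'")
    if weights is None:
        return base
    kgm = kgm_encode(g, weights)
    return EncodedInput(
        np.concatenate([base.array, kgm.array], axis=1), base.encoding_kind + "+kgm"
    )


def write_weights(w: WeightVector, path: str | Path) -> None:
    pd.DataFrame({"marker": w.markers, "w": w.w}).to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path) -> WeightVector:
    df = pd.read_csv(path, sep="\t", dtype={"marker": str})
    return WeightVector(list(df["marker"]), df["w"].to_numpy(np.float64))
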