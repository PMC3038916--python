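"""Masking of likely-miscalled bases in a designated species of an alignment.

Two strategies are provided. The baseline masks every base whose quality
(bin representative, raw phred units) falls below a threshold — the
default threshold of 20 masks bins 0–3 exactly. The optional classifier is
a logistic regression over the base's quality plus the phylogenetic error
log-odds score (window covariates — local G+C, flanking-quality summaries
— are available behind a flag but off by default: they add little once
quality and log-odds are in the model).

Masked bases become ``N``; the quality track and alignment geometry are
never altered, so masking is reversible given the decision log.
Polymorphism-weighted (fractional) training labels are supported as
likelihood weights, matching the confusion-adjustment convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .align_io import (
    GAP,
    QualityAlignmentBlock,
    bin_representative,
    decode_quality_char,
)
from .phylo_error import ErrorMatrix, PhyloModel, error_logodds

__all__ = [
    "MaskDecision",
    "RegressionModel",
    "mask_by_threshold",
    "extract_features",
    "feature_frame",
    "train_classifier",
    "predict_mask",
    "DEFAULT_COVARIATES",
]

DEFAULT_COVARIATES = ("quality", "logodds", "logodds_missing")
WINDOW_COVARIATES = ("gc", "min_quality", "mean_quality")


@dataclass
class MaskDecision:
    """Record of one masking decision for a single base."""

    species: str
    block_index: int
    column: int
    original_base: str
    quality: int  # bin
    masked: bool
    probability: Optional[float] = None  # P(error) in regression mode
    covariates: Optional[dict[str, float]] = None


def mask_by_threshold(
    block: QualityAlignmentBlock,
    species: str,
    threshold: int,
    block_index: int = 0,
) -> tuple[QualityAlignmentBlock, list[MaskDecision]]:
    """Mask bases of *species* whose quality representative is < *threshold*.

    Thresholds are raw phred units compared against the bin lower bound,
    so ``threshold=20`` masks bins 0–3. Qualities and geometry are
    unchanged; only base characters become ``N``.
    """
    row = block.row(species)
    if row.quality is None:
        raise ValueError(f"{species}: no quality track")
    out = block.copy()
    orow = out.row(species)
    text = list(orow.text)
    decisions = []
    for i, (c, qc) in enumerate(zip(orow.text, orow.quality)):
        if c == GAP:
            continue
        b = decode_quality_char(qc)
        masked = b is not None and bin_representative(b) < threshold and c != "N"
        if masked:
            text[i] = "N"
        decisions.append(
            MaskDecision(
                species=species,
                block_index=block_index,
                column=i,
                original_base=c,
                quality=b if b is not None else 9,
                masked=masked,
            )
        )
    orow.text = "".join(text)
    return out, decisions


def _window_stats(row, column: int, window: int) -> tuple[float, float, float]:
    """(gc, min_quality, mean_quality) over non-gap bases within *window*."""
    lo = max(column - window, 0)
    hi = min(column + window + 1, len(row.text))
    bases = []
    quals = []
    for i in range(lo, hi):
        c = row.text[i]
        if c == GAP:
            continue
        bases.append(c)
        if row.quality is not None:
            b = decode_quality_char(row.quality[i])
            if b is not None:
                quals.append(bin_representative(b))
    gc = sum(1 for c in bases if c in "GCgc") / len(bases) if bases else 0.0
    minq = float(min(quals)) if quals else 0.0
    meanq = float(np.mean(quals)) if quals else 0.0
    return gc, minq, meanq


def extract_features(
    block: QualityAlignmentBlock,
    species: str,
    column: int,
    model: Optional[PhyloModel] = None,
    M: Optional[ErrorMatrix] = None,
    window: int = 10,
    include_window: bool = False,
    tree_species: Optional[Sequence[str]] = None,
    optimize_rho: bool = True,
) -> dict[str, float]:
    """Feature vector for one base: quality, log-odds, optional window stats.

    When the column has no aligned partners on the tree the log-odds is
    undefined; it is imputed as 0 with the ``logodds_missing`` indicator
    set, so the regression can learn a separate intercept for such bases.
    """
    row = block.row(species)
    base = row.text[column]
    if base == GAP:
        raise ValueError("cannot extract features at a gap")
    b = decode_quality_char(row.quality[column]) if row.quality else None
    feats: dict[str, float] = {
        "quality": float(bin_representative(b)) if b is not None else 0.0
    }
    logodds = None
    if model is not None and M is not None and base not in ("N",):
        names = set(tree_species or model.leaf_names())
        col = {
            r.species: r.text[column]
            for r in block.rows
            if r.species in names and r.text[column] != GAP
        }
        if species in col:
            logodds = error_logodds(col, species, model, M, optimize_rho=optimize_rho)
    feats["logodds"] = float(logodds) if logodds is not None else 0.0
    feats["logodds_missing"] = 0.0 if logodds is not None else 1.0
    if include_window:
        gc, minq, meanq = _window_stats(row, column, window)
        feats["gc"] = gc
        feats["min_quality"] = minq
        feats["mean_quality"] = meanq
    return feats


def feature_frame(
    block: QualityAlignmentBlock,
    species: str,
    columns: Optional[Iterable[int]] = None,
    **kwargs,
) -> pd.DataFrame:
    """Feature rows for every (or the given) non-gap columns of *species*."""
    row = block.row(species)
    if columns is None:
        columns = [i for i, c in enumerate(row.text) if c != GAP]
    rows = []
    for i in columns:
        feats = extract_features(block, species, i, **kwargs)
        feats["column"] = i
        rows.append(feats)
    return pd.DataFrame(rows)


@dataclass
class RegressionModel:
    """Fitted logistic regression: intercept plus one slope per covariate."""

    coefficients: np.ndarray  # [intercept, *slopes]
    covariates: tuple[str, ...]
    n: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.covariates) + 1:
            raise ValueError("coefficient length must be len(covariates) + 1")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("non-finite coefficients")

    def design(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.covariates if c not in X.columns]
        if missing:
            raise ValueError(f"missing covariates: {missing}")
        mat = np.column_stack(
            [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in self.covariates]
        )
        return mat

    def predict_proba(self, X: pd.DataFrame) -> np.ndarray:
        eta = self.design(X) @ self.coefficients
        return 1.0 / (1.0 + np.exp(-eta))

    def to_tsv(self, path: Union[str, Path]) -> None:
        names = ("intercept",) + self.covariates
        pd.DataFrame({"covariate": names, "coefficient": self.coefficients}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: Union[str, Path]) -> "RegressionModel":
        df = pd.read_csv(path, sep="\t")
        if df.iloc[0]["covariate"] != "intercept":
            raise ValueError("first row must be the intercept")
        return cls(
            coefficients=df["coefficient"].to_numpy(dtype=float),
            covariates=tuple(df["covariate"].iloc[1:]),
        )


def train_classifier(
    X: pd.DataFrame,
    y: Sequence[float],
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    weights: Optional[Sequence[float]] = None,
) -> RegressionModel:
    """Maximum-likelihood logistic fit (IRLS via statsmodels GLM).

    *y* may be fractional (polymorphism-weighted error indicators in
    [0, 1]); *weights* are likelihood weights. Deterministic given input
    order. Raises on single-class labels; on perfect separation falls back
    to a lightly ridge-penalized fit (alpha 1e-6) with a warning.
    """
    import statsmodels.api as sm

    covariates = tuple(c for c in covariates if c in X.columns)
    if not covariates:
        raise ValueError("no usable covariates")
    y = np.asarray(y, dtype=float)
    if np.all(y <= 0) or np.all(y >= 1):
        raise ValueError("training labels are single-class")
    design = np.column_stack(
        [np.ones(len(X))] + [X[c].to_numpy(dtype=float) for c in covariates]
    )
    w = np.asarray(weights, dtype=float) if weights is not None else None
    glm = sm.GLM(
        y, design, family=sm.families.Binomial(),
        var_weights=w if w is not None else None,
    )
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = glm.fit(tol=1e-8, maxiter=200)
        coefs = np.asarray(res.params)
        converged = bool(res.converged)
        if not np.all(np.isfinite(coefs)) or np.abs(coefs).max() > 1e6:
            raise ValueError("divergent fit")
    except Exception:
        warnings.warn("separation or divergence; refitting with ridge penalty")
        res = glm.fit_regularized(alpha=1e-6, L1_wt=0.0)
        coefs = np.asarray(res.params)
        converged = False
    return RegressionModel(
        coefficients=coefs, covariates=covariates, n=len(y), converged=converged
    )


def predict_mask(
    block: QualityAlignmentBlock,
    species: str,
    model: RegressionModel,
    cutoff: float,
    block_index: int = 0,
    phylo: Optional[PhyloModel] = None,
    M: Optional[ErrorMatrix] = None,
    **feature_kwargs,
) -> tuple[QualityAlignmentBlock, list[MaskDecision]]:
    """Mask bases where the regression predicts P(error) > *cutoff*.

    ``cutoff=1`` is the identity, ``cutoff=0`` masks every maskable base;
    sweeping the cutoff traces the classifier's ROC curve.
    """
    feats = feature_frame(
        block, species, model=phylo, M=M, **feature_kwargs
    )
    if feats.empty:
        return block.copy(), []
    probs = model.predict_proba(feats)
    out = block.copy()
    orow = out.row(species)
    text = list(orow.text)
    decisions = []
    for (_, frow), p in zip(feats.iterrows(), probs):
        i = int(frow["column"])
        c = orow.text[i]
        masked = bool(p > cutoff) and c != "N"
        if masked:
            text[i] = "N"
        b = decode_quality_char(orow.quality[i]) if orow.quality else None
        decisions.append(
            MaskDecision(
                species=species,
                block_index=block_index,
                column=i,
                original_base=c,
                quality=b if b is not None else 9,
                masked=masked,
                probability=float(p),
                covariates={
                    k: float(frow[k]) for k in model.covariates if k in frow
                },
            )
        )
    orow.text = "".join(text)
    return out, decisions
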