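"""Principal components of the genotype matrix.

Markers are mean-imputed (missing calls take the marker mean code),
centered, and by default scaled to unit variance per marker (zero-variance
markers are dropped); components come from the eigendecomposition of the
individual-by-individual covariance, computed via SVD.  Each component is
oriented so its largest-magnitude marker loading is positive, making score
plots reproducible across BLAS backends.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as st

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PcaResult:
    scores: pd.DataFrame           # individuals x PCs, indexed by individual id
    explained_variance: np.ndarray  # fractions, nonincreasing
    eigenvalues: np.ndarray


def run_pca(matrix: GenotypeMatrix, n_components: int = 10,
            scale: str = "unit") -> PcaResult:
    """PCA of a (QC-passed) genotype matrix.

    ``scale``: "unit" divides each centered marker by its standard
    deviation; "drift" uses sqrt(2p(1-p)) (the drift normalization); "none"
    centers only.  ``n_components`` beyond the matrix rank is truncated
    with a warning.
    """
    X = matrix.codes.astype(float)
    X[matrix.codes == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    X -= col_mean

    if scale == "unit":
        sd = X.std(axis=0, ddof=0)
    elif scale == "drift":
        p = col_mean / 2.0
        sd = np.sqrt(2.0 * p * (1.0 - p))
    elif scale == "none":
        sd = np.ones(X.shape[1])
    else:
        raise ValueError(f"unknown scale mode {scale!r}")
    keep = sd > 0
    if not keep.all():
        logger.info("dropping %d zero-variance markers before PCA", (~keep).sum())
    X = X[:, keep] / sd[keep]

    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(f"requested {n_components} components but rank is {rank}; truncating")
        n_components = rank
    eigenvalues = s ** 2  # eigenvalues of the individual x individual Gram matrix
    total = eigenvalues.sum()
    explained = eigenvalues[:n_components] / total if total > 0 else eigenvalues[:n_components]

    scores = U[:, :n_components] * s[:n_components]
    # orient: largest-|loading| entry of each component positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            scores[:, k] *= -1.0
    frame = pd.DataFrame(scores, index=matrix.individual_ids,
                         columns=[f"PC{k + 1}" for k in range(n_components)])
    return PcaResult(scores=frame, explained_variance=explained,
                     eigenvalues=eigenvalues[:n_components])


def group_overlay(pca: PcaResult, labels: pd.Series,
                  ellipse_level: float = 0.95) -> pd.DataFrame:
    """Join PC scores with group labels for plotting.

    Raises on id mismatch.  The returned frame carries one row per ewe plus
    per-group 95% concentration-ellipse parameters (center, axes, angle) as
    frame attrs under ``.attrs["ellipses"]``.
    """
    ids = pca.scores.index
    missing = ids.difference(labels.index)
    if len(missing) or len(labels.index.difference(ids)):
        raise ValueError(f"id mismatch between PCA scores and group labels: "
                         f"{list(missing)[:5]}")
    out = pca.scores.copy()
    out["group"] = labels.reindex(ids)
    ellipses = {}
    if out.shape[1] >= 3:  # at least 2 PCs + group
        chi2_r = np.sqrt(st.chi2.ppf(ellipse_level, df=2))
        for group, grp in out.groupby("group"):
            xy = grp[["PC1", "PC2"]].to_numpy()
            if xy.shape[0] < 3:
                continue
            center = xy.mean(axis=0)
            cov = np.cov(xy.T)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            ellipses[group] = {
                "center": center.tolist(),
                "semi_axes": (chi2_r * np.sqrt(np.maximum(evals, 0))).tolist(),
                "angle_deg": float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0]))),
            }
    out.attrs["ellipses"] = ellipses
    return out


def plot_scores(overlay: pd.DataFrame, explained: np.ndarray, path: str) -> None:
    """Scatter of PC1 vs PC2 colored by group, with variance fractions in
    the axis labels."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    colors = {"high": "tab:blue", "low": "tab:red"}
    for group, grp in overlay.groupby("group"):
        ax.scatter(grp["PC1"], grp["PC2"], s=18, label=group,
                   color=colors.get(group, "gray"), alpha=0.8)
    ax.set_xlabel(f"PC1 ({100 * explained[0]:.1f}%)")
    if len(explained) > 1:
        ax.set_ylabel(f"PC2 ({100 * explained[1]:.1f}%)")
    ax.legend(title="fecundity")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
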