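"""Expression filtering, DEG calling, SLFDR gene scores, and sample distances.

Differential-expression results arrive as per-contrast tables of
(gene_id, log2fc, fdr), with the contrast oriented low-pH vs high-pH: a
positive log2 fold change means higher expression at the lower pH.  Genes
are kept in the universe when they reach >= 1 count per million in at least
two replicates.  DEGs are called at FDR < .01 and every gene receives a
signed ln(FDR) score,

    SLFDR = ln(FDR) * sign(log2FC),

so a significantly *up*regulated gene gets a strongly *negative* score (ln of
a small FDR) — that printed orientation is kept as the default and can be
flipped with ``flip_sign`` for the conventional -ln convention.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DETable",
    "cpm_filter",
    "slfdr",
    "call_degs",
    "sample_distances",
    "read_de_tsv",
]

DEG_ALPHA_DEFAULT = 0.01
FDR_FLOOR_DEFAULT = 1e-300


@dataclass
class DETable:
    """Per-gene DE results for one strain and one low-vs-high pH contrast."""

    frame: pd.DataFrame  # columns gene_id, log2fc, fdr
    strain: str
    contrast: tuple[str, str]  # (low_ph, high_ph)

    def __post_init__(self) -> None:
        required = {"gene_id", "log2fc", "fdr"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"DE table missing columns {sorted(missing)}")
        if self.frame["gene_id"].duplicated().any():
            dupes = self.frame.loc[self.frame["gene_id"].duplicated(), "gene_id"]
            raise ValueError(f"duplicate gene ids in DE table: {list(dupes[:5])}")
        fdr = self.frame["fdr"].to_numpy(dtype=float)
        if np.any((fdr < 0) | (fdr > 1)):
            raise ValueError("FDR values must lie in [0, 1]")

    @property
    def genes(self) -> frozenset[str]:
        return frozenset(self.frame["gene_id"])


def cpm_filter(cpm: pd.DataFrame, min_cpm: float = 1.0, min_reps: int = 2) -> frozenset[str]:
    """Gene universe after the expression filter.

    Keeps genes with CPM >= ``min_cpm`` in at least ``min_reps`` samples.
    ``cpm`` is genes x samples.
    """
    if cpm.shape[1] < min_reps:
        raise ValueError(
            f"matrix has {cpm.shape[1]} samples but min_reps={min_reps}"
        )
    hits = (cpm.to_numpy(dtype=float) >= min_cpm).sum(axis=1)
    return frozenset(cpm.index[hits >= min_reps])


def slfdr(
    fdr: float,
    log2fc: float,
    fdr_floor: float = FDR_FLOOR_DEFAULT,
    flip_sign: bool = False,
) -> float:
    """Signed ln(FDR) gene-level score.

    Returns ``ln(max(fdr, fdr_floor)) * sign(log2fc)``.  A zero fold change
    has no sign, so the score is 0 with a warning; such genes are never DEGs
    and the convention keeps them rankable.
    """
    if not 0.0 <= fdr <= 1.0:
        raise ValueError(f"fdr must be in [0, 1], got {fdr}")
    if log2fc == 0:
        warnings.warn("log2fc = 0: SLFDR sign undefined, score set to 0", stacklevel=2)
        return 0.0
    score = math.log(max(fdr, fdr_floor)) * math.copysign(1.0, log2fc)
    return -score if flip_sign else score


def call_degs(
    table: DETable,
    alpha: float = DEG_ALPHA_DEFAULT,
    fdr_floor: float = FDR_FLOOR_DEFAULT,
    flip_sign: bool = False,
) -> pd.DataFrame:
    """Label DEGs and attach SLFDR scores to every gene of the table.

    Returns a frame indexed by gene_id with columns ``log2fc``, ``fdr``,
    ``slfdr``, ``deg_label`` (up / down / none).  ``up`` means FDR < alpha and
    log2fc > 0, i.e. higher expression at the low-pH side of the contrast.
    """
    frame = table.frame.set_index("gene_id")[["log2fc", "fdr"]].copy()
    log2fc = frame["log2fc"].to_numpy(dtype=float)
    fdr = frame["fdr"].to_numpy(dtype=float)
    sign = np.sign(log2fc)
    scores = np.log(np.maximum(fdr, fdr_floor)) * sign
    if flip_sign:
        scores = -scores
    frame["slfdr"] = scores
    sig = fdr < alpha
    labels = np.where(sig & (log2fc > 0), "up", np.where(sig & (log2fc < 0), "down", "none"))
    frame["deg_label"] = labels
    return frame


def sample_distances(
    cpm: pd.DataFrame, pseudocount: float = 1.0, center: str = "mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlations and Euclidean distances among samples.

    Expression is transformed to ``log2(CPM + pseudocount)`` and centered per
    gene (mean by default, median optionally) before computing both matrices
    on the sample columns.  A zero-variance sample yields NaN correlations for
    its pairs (flagged with a warning).
    """
    if cpm.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    if center not in ("mean", "median"):
        raise ValueError(f"center must be 'mean' or 'median', got {center!r}")
    x = np.log2(cpm.to_numpy(dtype=float) + pseudocount)
    loc = x.mean(axis=1, keepdims=True) if center == "mean" else np.median(x, axis=1, keepdims=True)
    x = x - loc
    samples = list(cpm.columns)

    sd = x.std(axis=0, ddof=0)
    if np.any(sd == 0):
        flat = [s for s, v in zip(samples, sd) if v == 0]
        warnings.warn(f"zero-variance samples, correlations undefined: {flat}", stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(x, rowvar=False)
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)

    diff = x[:, :, None] - x[:, None, :]
    eucl = np.sqrt((diff**2).sum(axis=0))
    pearson = pd.DataFrame(corr, index=samples, columns=samples)
    euclid = pd.DataFrame(eucl, index=samples, columns=samples)
    return pearson, euclid


def read_de_tsv(path, strain: str, contrast: tuple[str, str]) -> DETable:
    """Read a DE table TSV (gene_id, log2fc, fdr) for one strain x contrast."""
    frame = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return DETable(frame=frame, strain=strain, contrast=tuple(contrast))
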