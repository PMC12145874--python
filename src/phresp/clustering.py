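"""Strain-pH enrichment groups and response-similarity clustering.

The composite enrichment calls of one strain and one pairwise pH contrast are
split into an enriched (En) and a depleted (Dp) group of affected gene-set
ids.  Groups are named ``<strain>_<low><En|Dp><high>`` with the pH values
truncated to their integer part (4.7 -> 4, 7.0 -> 7, 8.2 -> 8), e.g.
``NPAL-12_7En8`` for sets enriched at pH 7.0 relative to pH 8.2 in strain
NPAL-12.  Pairwise group dissimilarity is the square-root-transformed Jaccard
distance on set presence/absence, d = sqrt(1 - |A n B| / |A u B|), which is
Euclidean-embeddable; groups are ordered by agglomerative clustering for
heatmap display.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentGroup",
    "group_label",
    "build_groups",
    "jaccard_sqrt_distance",
    "order_groups",
    "export_heatmap",
]


@dataclass(frozen=True)
class EnrichmentGroup:
    """Affected gene sets for one strain, one pH contrast, one direction."""

    strain: str
    contrast: tuple[str, str]  # (low_ph, high_ph)
    direction: str  # "En" | "Dp"
    members: frozenset[str]

    @property
    def label(self) -> str:
        return group_label(self.strain, self.contrast, self.direction)


def _truncate_ph(ph: str | float) -> str:
    return str(int(math.floor(float(ph))))


def group_label(strain: str, contrast: tuple[str, str], direction: str) -> str:
    """Group name: strain, then the direction code between the truncated pHs."""
    if direction not in ("En", "Dp"):
        raise ValueError(f"direction must be 'En' or 'Dp', got {direction!r}")
    low, high = contrast
    return f"{strain}_{_truncate_ph(low)}{direction}{_truncate_ph(high)}"


def build_groups(
    composite: pd.DataFrame, strain: str, contrast: tuple[str, str]
) -> tuple[EnrichmentGroup, EnrichmentGroup]:
    """Split one strain x contrast's composite calls into (En, Dp) groups.

    ``composite`` needs columns set_id, enriched, depleted.  A set flagged
    both appears in both groups; empty groups are retained.
    """
    en = frozenset(composite.loc[composite["enriched"].astype(bool), "set_id"])
    dp = frozenset(composite.loc[composite["depleted"].astype(bool), "set_id"])
    return (
        EnrichmentGroup(strain=strain, contrast=tuple(contrast), direction="En", members=en),
        EnrichmentGroup(strain=strain, contrast=tuple(contrast), direction="Dp", members=dp),
    )


def jaccard_sqrt_distance(
    groups: Sequence[EnrichmentGroup] | dict[str, Iterable[str]],
) -> pd.DataFrame:
    """Square-root-transformed Jaccard dissimilarity matrix among groups.

    For groups A, B with a = |A n B|, b = |A \\ B|, c = |B \\ A| the
    similarity is s = a / (a + b + c) and the distance sqrt(1 - s).  Two empty
    groups are identical by convention (distance 0, logged); an empty vs a
    non-empty group is maximally distant (1).
    """
    if isinstance(groups, dict):
        labeled = {label: frozenset(m) for label, m in groups.items()}
    else:
        labeled = {g.label: g.members for g in groups}
        if len(labeled) < len(groups):
            raise ValueError("duplicate group labels")
    labels = list(labeled)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a_set, b_set = labeled[labels[i]], labeled[labels[j]]
            union = len(a_set | b_set)
            if union == 0:
                logger.info("empty groups %s and %s: distance 0 by convention",
                            labels[i], labels[j])
                d = 0.0
            else:
                d = math.sqrt(1.0 - len(a_set & b_set) / union)
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


def order_groups(
    matrix: pd.DataFrame, linkage: str = "average"
) -> tuple[list[str], np.ndarray]:
    """Agglomerative leaf order of the groups (heatmap/dendrogram axis order).

    Labels are sorted lexicographically before linkage so ties in merge
    distance resolve deterministically.  Returns (ordered labels, scipy
    linkage matrix over the sorted labels).
    """
    values = matrix.to_numpy(dtype=float)
    if not np.allclose(values, values.T):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(values), 0.0):
        raise ValueError("distance matrix must have a zero diagonal")
    labels = sorted(matrix.index)
    ordered_matrix = matrix.loc[labels, labels].to_numpy(dtype=float)
    condensed = squareform(ordered_matrix, checks=False)
    link = hierarchy.linkage(condensed, method=linkage)
    leaves = hierarchy.leaves_list(link)
    return [labels[i] for i in leaves], link


def export_heatmap(
    matrix: pd.DataFrame,
    order: Sequence[str],
    path: str | Path,
    render_png: bool = True,
) -> dict[str, Path]:
    """Write the ordered distance matrix as TSV and, optionally, a raster heatmap.

    ``path`` is the stem; ``<stem>.tsv`` always holds the exact ordered
    matrix, ``<stem>.png`` the rendered heatmap whose fill gradient starts at
    the minimum estimated (off-diagonal) distance.
    """
    path = Path(path)
    if set(order) != set(matrix.index):
        raise ValueError("order must be a permutation of the matrix labels")
    ordered = matrix.loc[list(order), list(order)]
    outputs: dict[str, Path] = {}
    tsv_path = path.with_suffix(".tsv")
    try:
        ordered.to_csv(tsv_path, sep="\t", index_label="group")
    except OSError as exc:
        raise OSError(f"failed writing heatmap TSV to {tsv_path}: {exc}") from exc
    outputs["tsv"] = tsv_path
    if render_png:
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        values = ordered.to_numpy(dtype=float)
        off_diag = values[~np.eye(len(values), dtype=bool)]
        vmin = float(off_diag.min()) if off_diag.size else 0.0
        fig, ax = plt.subplots(figsize=(max(4, 0.3 * len(order)),) * 2)
        im = ax.imshow(values, vmin=vmin, vmax=max(values.max(), vmin + 1e-12),
                       cmap="viridis")
        ax.set_xticks(range(len(order)), labels=list(order), rotation=90, fontsize=6)
        ax.set_yticks(range(len(order)), labels=list(order), fontsize=6)
        fig.colorbar(im, ax=ax, label="sqrt(1 - Jaccard)")
        fig.tight_layout()
        png_path = path.with_suffix(".png")
        try:
            fig.savefig(png_path, dpi=150)
        except OSError as exc:
            raise OSError(f"failed writing heatmap image to {png_path}: {exc}") from exc
        finally:
            plt.close(fig)
        outputs["png"] = png_path
    return outputs
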