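"""Unsupervised hierarchical clustering of rank profiles.

Because the profiles are within-sample ranks, samples from different
platforms (microarray and fragment-analysis cohorts together) cluster in a
common feature space with no harmonization step: the platform tag never
enters the distance computation.  The default metric is Euclidean distance
on the 57-dimensional rank vectors with average linkage; Spearman
dissimilarity (1 - rank correlation) and complete/Ward linkage are options.

Cluster/subtype agreement is scored with the adjusted Rand index, which is
1 only for identical partitions (up to relabeling) and has expectation 0
under chance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .errors import ValidationError
from .io import SampleLabels
from .ranking import RankProfiles

_DISTANCES = ("euclidean", "spearman")
_LINKAGES = ("average", "complete", "ward")


@dataclass
class ClusterResult:
    """Linkage tree over samples plus a deterministic heatmap ordering."""

    sample_ids: list[str]  # order fed to the linkage (sorted by sample_id)
    linkage: np.ndarray  # scipy (n-1) x 4 merge matrix
    distance: str
    linkage_method: str

    @property
    def leaf_order(self) -> list[str]:
        return [self.sample_ids[i] for i in leaves_list(self.linkage)]

    def cut(self, k: int) -> dict[str, int]:
        """Flat assignment into at most k clusters."""
        flat = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.sample_ids, (int(c) for c in flat)))


def cluster_samples(
    profiles: RankProfiles, distance: str = "euclidean", linkage: str = "average"
) -> ClusterResult:
    """Hierarchically cluster samples by their rank profiles.

    Samples are processed in sorted-sample_id order, so the tree (and every
    export derived from it) is a pure function of the profile set.
    Identical profiles are at distance 0 and merge at height 0.
    """
    if distance not in _DISTANCES:
        raise ValidationError(f"unknown distance {distance!r}; allowed: {_DISTANCES}")
    if linkage not in _LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; allowed: {_LINKAGES}")
    if linkage == "ward" and distance != "euclidean":
        raise ValidationError("ward linkage requires euclidean distance")
    ids = sorted(profiles.sample_ids)
    if len(ids) < 2:
        raise ValidationError("clustering requires at least 2 samples")
    X = profiles.ranks[ids].to_numpy().T
    if distance == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        # profiles are already ranks, so Pearson correlation of the vectors
        # IS the Spearman correlation of the underlying expression
        d = pdist(X, metric="correlation")
    Z = scipy_linkage(d, method=linkage)
    return ClusterResult(ids, Z, distance, linkage)


def concordance(assignment: Mapping[str, int], labels: SampleLabels) -> float:
    """Adjusted Rand index between a flat clustering and the true subtypes."""
    a, b = set(assignment), set(labels.labels)
    if a != b:
        raise ValidationError(
            f"sample sets differ; only in assignment: {sorted(a - b)}, "
            f"only in labels: {sorted(b - a)}"
        )
    order = sorted(a)
    return float(
        adjusted_rand_score([labels[s] for s in order], [assignment[s] for s in order])
    )


def export_heatmap(
    profiles: RankProfiles,
    result: ClusterResult,
    labels: SampleLabels | None,
    matrix_path: str | Path,
    image_path: str | Path | None = None,
) -> pd.DataFrame:
    """Write the genes x leaf-ordered-samples rank matrix (TSV) and a heatmap.

    The TSV holds the rank values verbatim (no rescaling) with columns in
    dendrogram leaf order — it is the testable artifact; the rendered image
    adds a subtype color bar when labels are given.
    """
    ordered = profiles.ranks[result.leaf_order]
    out = ordered.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.10g")
    if image_path is not None:
        _render_heatmap(ordered, labels, image_path)
    return ordered


def _render_heatmap(ordered: pd.DataFrame, labels, image_path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    col_colors = None
    if labels is not None:
        subs = sorted({labels[s] for s in ordered.columns})
        palette = dict(zip(subs, sns.color_palette("tab10", len(subs))))
        col_colors = pd.Series(
            {s: palette[labels[s]] for s in ordered.columns}, name="subtype"
        )
    g = sns.clustermap(
        ordered,
        row_cluster=False,
        col_cluster=False,
        col_colors=col_colors,
        cmap="viridis",
        xticklabels=False,
        yticklabels=False,
        cbar_kws={"label": "within-sample rank"},
    )
    g.savefig(image_path, dpi=120)
    plt.close("all")
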