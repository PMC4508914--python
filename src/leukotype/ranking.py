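"""Within-sample rank transformation of the marker-gene panel.

The classifier never sees raw expression values.  For every sample, the 57
marker-gene values are sorted from low to high and each gene receives its
ascending rank (lowest expression -> rank 1).  Because ranks are invariant
under any strictly increasing per-sample transformation, a rank profile is
directly comparable across platforms (microarray vs. capillary
fragment-analysis), across labs and across patients, with no reference
cohort — this is what makes a single-sample, individualized diagnosis
possible, and it acts as an internal normalization similar in spirit to
quantile normalization.

Ties — most importantly the many exact zeros that fragment-analysis assays
produce for undetected genes — receive the average of the ranks they span,
so every profile sums to exactly 57*58/2 = 1653.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DimensionError, ValidationError
from .io import ExpressionMatrix

#: Number of marker genes in the classifier's feature space.
PANEL_SIZE = 57

#: Rank total of a 57-gene profile under the average-tie rule.
RANK_SUM = PANEL_SIZE * (PANEL_SIZE + 1) // 2  # 1653

_TIE_RULES = ("average", "ordinal")


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered set of the 57 marker gene symbols.

    The order is fixed when a model is trained and persisted with it; rank
    vectors are always aligned to this order.
    """

    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != PANEL_SIZE:
            raise DimensionError(
                f"marker panel must hold exactly {PANEL_SIZE} genes, "
                f"got {len(self.genes)}"
            )
        if len(set(self.genes)) != PANEL_SIZE:
            seen: set[str] = set()
            dups = [g for g in self.genes if g in seen or seen.add(g)]
            raise ValidationError(f"duplicate marker genes in panel: {dups}")

    def __len__(self) -> int:
        return PANEL_SIZE

    def __iter__(self):
        return iter(self.genes)


@dataclass
class RankProfiles:
    """Per-sample rank vectors over a marker panel.

    ``ranks`` is a genes x samples DataFrame whose index equals the panel
    order; column ``s`` is sample ``s``'s rank profile.
    """

    panel: MarkerPanel
    ranks: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ranks.columns)

    def profile(self, sample_id: str) -> np.ndarray:
        return self.ranks[sample_id].to_numpy()

    def subset(self, sample_ids) -> "RankProfiles":
        return RankProfiles(self.panel, self.ranks[list(sample_ids)])


def rank_sample(values, tie_rule: str = "average") -> np.ndarray:
    """Rank one sample's marker-gene expression vector, ascending.

    Parameters
    ----------
    values
        Length-57 vector of finite, non-negative expression values;
        undetected genes must be encoded as 0.
    tie_rule
        ``"average"`` (default) assigns tied values the mean of the ranks
        they span, preserving the rank-sum of 1653; ``"ordinal"`` breaks
        ties by position.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size != PANEL_SIZE:
        raise DimensionError(
            f"expected a length-{PANEL_SIZE} vector, got shape {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise ValidationError("expression values must be finite")
    if (v < 0).any():
        raise ValidationError(
            f"negative expression value {v[v < 0][0]!r}; "
            "undetected genes must be encoded as 0"
        )
    if tie_rule not in _TIE_RULES:
        raise ValidationError(f"unknown tie rule {tie_rule!r}; allowed: {_TIE_RULES}")
    return rankdata(v, method=tie_rule).astype(float)


def rank_matrix(
    m: ExpressionMatrix,
    panel: MarkerPanel,
    tie_rule: str = "average",
    scale: bool = False,
) -> RankProfiles:
    """Rank every sample of an expression matrix over the marker panel.

    Ranking is strictly within-sample (column-wise); samples never see each
    other.  All panel genes must be present as rows — missing genes raise,
    they are never silently dropped.  With ``scale=True`` ranks are divided
    by 57 to land in (0, 1]; the default feeds raw ranks 1..57 downstream.
    """
    missing = [g for g in panel.genes if g not in m.values.index]
    if missing:
        raise ValidationError(f"panel genes absent from expression matrix: {missing}")
    sub = m.values.loc[list(panel.genes)]
    if sub.columns.empty:
        ranked = np.empty((PANEL_SIZE, 0))
    else:
        ranked = np.column_stack(
            [rank_sample(sub[c].to_numpy(), tie_rule=tie_rule) for c in sub.columns]
        )
    if scale:
        ranked = ranked / PANEL_SIZE
    frame = pd.DataFrame(ranked, index=list(panel.genes), columns=sub.columns)
    return RankProfiles(panel, frame)
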