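"""Synthetic cohorts with the statistical structure the method assumes.

The generator draws a latent log-normal expression state per sample over
the 57-gene marker panel, shifts each subtype's disjoint signature genes
upward, and renders the latent state onto a platform through a strictly
monotone power-law distortion v -> a·v^b followed by threshold dropout
(values below the detection floor become exact zeros — the value-dependent
censoring fragment-analysis assays show for lowly expressed genes).

Defaults mirror the study conditions: the cohort's class imbalance copies
the clinical cohort (many ETV6-RUNX1, five MLL-rearrangement samples); the
"Others" class carries no signature of its own but is molecularly
heterogeneous — a configurable fraction of its samples partially express a
random known subtype's signature, like the lesion-negative patients whose
profiles resemble BCR-ABL1-positive disease — which makes it the hardest
class to recover, as in real cohorts; and the two platforms share the
latent state so that, without dropout, their rank profiles are identical by
construction.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .afa import PanelDefinition, PeakTable
from .errors import ConfigError
from .io import SUBTYPES, ExpressionMatrix, SampleLabels
from .ranking import MarkerPanel

#: Class sizes of the 160-patient clinical fragment-analysis cohort.
DEFAULT_COHORT: dict[str, int] = {
    "ETV6-RUNX1": 54,
    "hyperdiploid >50": 37,
    "T-ALL": 20,
    "BCR-ABL1": 17,
    "TCF3-PBX1": 15,
    "Others": 12,
    "MLL rearrangement": 5,
}

#: Monotone platform distortions v -> a·v^b and detection floors (on the
#: transformed scale).  The microarray renders the latent state faithfully
#: with no dropout; the fragment-analysis platform compresses/rescales it
#: and loses lowly expressed genes.
DEFAULT_PLATFORMS: dict[str, tuple[float, float]] = {
    "microarray": (1.0, 1.0),
    "AFA": (3.0, 0.4),
}
DEFAULT_DROPOUT: dict[str, float] = {"microarray": 0.0, "AFA": 12.0}


@dataclass
class SimulationConfig:
    """Knobs of the cohort generator.

    signature_strength is the mean log-expression shift (in units of
    noise_sd when noise_sd=1) applied to a subtype's signature genes;
    baseline_log_range spans typical log-expression baselines per gene;
    peak_jitter_bp is the uniform fragment-size measurement error used when
    rendering electropherogram peaks.
    """

    n_per_subtype: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_COHORT))
    signature_strength: float = 2.0
    signature_size: int = 8
    noise_sd: float = 1.0
    baseline_log_range: tuple[float, float] = (3.0, 7.5)
    platform_transforms: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PLATFORMS)
    )
    dropout_threshold: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DROPOUT)
    )
    peak_jitter_bp: float = 0.5
    #: Fraction of "Others" samples that partially express another subtype's
    #: signature (the "looks like BCR-ABL1" phenomenon of lesion-negative
    #: patients: 2 of the 12 such clinical samples), and how much of that
    #: signature they carry.
    others_mimic_prob: float = 2 / 12
    others_mimic_fraction: float = 0.75
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_per_subtype or all(n <= 0 for n in self.n_per_subtype.values()):
            raise ConfigError("n_per_subtype must request at least one sample")
        unknown = [s for s in self.n_per_subtype if s not in SUBTYPES]
        if unknown:
            raise ConfigError(f"unknown subtypes in n_per_subtype: {unknown}")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be positive")
        if self.signature_strength < 0:
            raise ConfigError("signature_strength must be >= 0")
        if self.signature_size <= 0:
            raise ConfigError("signature_size must be positive")
        if not (0.0 <= self.others_mimic_prob <= 1.0):
            raise ConfigError("others_mimic_prob must lie in [0, 1]")
        if not (0.0 <= self.others_mimic_fraction <= 1.0):
            raise ConfigError("others_mimic_fraction must lie in [0, 1]")
        for tag, (a, b) in self.platform_transforms.items():
            if a <= 0 or b <= 0:
                raise ConfigError(
                    f"platform {tag!r}: transform parameters must be positive "
                    "(the map must be strictly increasing)"
                )


def _signature_assignment(panel: MarkerPanel, cfg: SimulationConfig) -> dict[str, list[int]]:
    """Disjoint signature gene indices per subtype; "Others" gets none."""
    signatured = [s for s in SUBTYPES if s != "Others" and s in cfg.n_per_subtype]
    need = len(signatured) * cfg.signature_size
    if need > len(panel.genes):
        raise ConfigError(
            f"signature_size {cfg.signature_size} x {len(signatured)} subtypes "
            f"needs {need} genes but the panel has {len(panel.genes)}"
        )
    return {
        s: list(range(i * cfg.signature_size, (i + 1) * cfg.signature_size))
        for i, s in enumerate(signatured)
    }


def _latent_cohort(
    panel: MarkerPanel, cfg: SimulationConfig, seed: int
) -> tuple[np.ndarray, SampleLabels, list[str]]:
    # baselines are properties of the genes, not of the cohort: they come
    # from a fixed internal stream so independently seeded cohorts share the
    # same underlying marker biology (training on one cohort must generalize
    # to another)
    lo, hi = cfg.baseline_log_range
    baseline = np.random.default_rng(715).uniform(lo, hi, size=len(panel.genes))
    rng = np.random.default_rng(seed)
    sig = _signature_assignment(panel, cfg)
    cols, sample_ids, labels = [], [], {}
    k = 0
    for subtype in SUBTYPES:
        for _ in range(int(cfg.n_per_subtype.get(subtype, 0))):
            k += 1
            sid = f"S{k:04d}"
            shift = np.zeros(len(panel.genes))
            if subtype in sig:
                shift[sig[subtype]] = cfg.signature_strength * cfg.noise_sd
            elif subtype == "Others" and sig and rng.random() < cfg.others_mimic_prob:
                # heterogeneous lesion-negative sample resembling a known
                # subtype: a diluted copy of a random signature
                mimic = list(sig)[int(rng.integers(len(sig)))]
                shift[sig[mimic]] = (
                    cfg.others_mimic_fraction * cfg.signature_strength * cfg.noise_sd
                )
            logv = baseline + shift + rng.normal(0.0, cfg.noise_sd, len(panel.genes))
            cols.append(np.exp(logv))
            sample_ids.append(sid)
            labels[sid] = subtype
    latent = np.column_stack(cols)
    return latent, SampleLabels(labels), sample_ids


def _render_platform(
    latent: np.ndarray, cfg: SimulationConfig, platform: str
) -> np.ndarray:
    try:
        a, b = cfg.platform_transforms[platform]
    except KeyError:
        raise ConfigError(
            f"platform {platform!r} has no transform; "
            f"known: {sorted(cfg.platform_transforms)}"
        ) from None
    v = a * latent**b
    thr = float(cfg.dropout_threshold.get(platform, 0.0))
    if thr > 0:
        v = np.where(v < thr, 0.0, v)
    return v


def simulate_cohort(
    cfg: SimulationConfig, platform: str = "microarray", panel: MarkerPanel | None = None
) -> tuple[ExpressionMatrix, SampleLabels]:
    """Draw one cohort and render it on a single platform."""
    if panel is None:
        from .afa import default_panel

        _, panel = default_panel()
    latent, labels, sample_ids = _latent_cohort(panel, cfg, cfg.seed)
    values = _render_platform(latent, cfg, platform)
    frame = pd.DataFrame(values, index=list(panel.genes), columns=sample_ids)
    return ExpressionMatrix(frame, platform=platform), labels


def simulate_paired_platforms(
    cfg: SimulationConfig,
    platforms: tuple[str, str] = ("microarray", "AFA"),
    panel: MarkerPanel | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SampleLabels]:
    """Render ONE latent cohort on two platforms.

    Platform B's raw values are a strictly monotone transform of platform
    A's (same latent draw), minus whatever its detection floor censors — so
    with dropout disabled the two matrices carry identical within-sample
    rank profiles by construction.
    """
    if panel is None:
        from .afa import default_panel

        _, panel = default_panel()
    latent, labels, sample_ids = _latent_cohort(panel, cfg, cfg.seed)
    mats = []
    for tag in platforms:
        values = _render_platform(latent, cfg, tag)
        frame = pd.DataFrame(values, index=list(panel.genes), columns=sample_ids)
        mats.append(ExpressionMatrix(frame, platform=tag))
    return mats[0], mats[1], labels


def without_dropout(cfg: SimulationConfig) -> SimulationConfig:
    """Copy of the config with every platform's detection floor disabled."""
    return replace(cfg, dropout_threshold={k: 0.0 for k in cfg.dropout_threshold})


def simulate_peaks(
    m: ExpressionMatrix,
    p: PanelDefinition,
    cfg: SimulationConfig,
    control_area: float = 100.0,
    failed_controls: tuple[str, ...] = (),
) -> list[PeakTable]:
    """Render an expression matrix as per-sample, per-panel peak tables.

    Every nonzero gene emits one peak per amplicon at the expected fragment
    length plus uniform jitter in ±peak_jitter_bp, with area equal to the
    gene's expression value.  Reference controls are injected at
    ``control_area`` unless named in ``failed_controls`` (QC scenarios).
    """
    half_spacing = p.min_spacing() / 2.0
    if cfg.peak_jitter_bp >= half_spacing:
        raise ConfigError(
            f"peak_jitter_bp {cfg.peak_jitter_bp} >= half the minimum panel "
            f"spacing ({half_spacing}); peaks would not be identifiable"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    tables: list[PeakTable] = []
    for sid in m.sample_ids:
        col = m.values[sid]
        for pid in p.panel_ids():
            peaks: list[tuple[float, float]] = []
            for a in p.in_panel(pid):
                if a.is_control:
                    area = 0.0 if a.gene in failed_controls else control_area
                else:
                    if a.gene not in col.index:
                        continue
                    area = float(col[a.gene])
                if area <= 0:
                    continue
                jitter = rng.uniform(-cfg.peak_jitter_bp, cfg.peak_jitter_bp)
                peaks.append((a.length + jitter, area))
            tables.append(PeakTable(sample_id=sid, panel_id=pid, peaks=peaks))
    return tables
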