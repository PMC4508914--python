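"""Computational rules of the multiplex fragment-analysis (AFA) assay.

The assay amplifies each marker gene with chimeric gene-specific/universal-
tag primers and resolves the products by capillary electrophoresis: the
fragment size identifies the gene, the peak area measures its expression.
This module encodes the parts of the assay that are pure computation:

* panel design validation — amplicon lengths within 137–316 bp, pairwise
  spacing of at least 4 bp within a panel, five reference controls per
  panel (endogenous B2M/PSMC4/GUSB for normalization, synthetic KanR and
  pcDNA3.1(+) to monitor the RT and PCR steps), full coverage of the
  57-gene marker set across 58 amplicons (PBX1 is assayed twice);
* peak-to-gene assignment by nearest expected fragment length within a
  tolerance (default ±1.5 bp — safe because design spacing is ≥4 bp);
* reference-control QC verdicts (KanR monitors both RT and PCR, so its
  absence means RT/PCR failure; pcDNA3.1(+) monitors PCR only, so its
  absence with KanR present is a PCR anomaly);
* standard-curve relative quantification (log–log linear calibration,
  normalized by the geometric mean of the endogenous references).

Genes with no matched peak get area 0 — the "undetected, labeled as zero"
convention that feeds the rank transform downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousPeakError,
    QuantificationError,
    ValidationError,
)
from .io import ExpressionMatrix
from .ranking import MarkerPanel

LENGTH_MIN = 137
LENGTH_MAX = 316
MIN_SPACING = 4

ENDOGENOUS_CONTROLS = ("B2M", "PSMC4", "GUSB")
EXTERNAL_CONTROLS = ("KanR", "pcDNA3.1(+)")
ALL_CONTROLS = ENDOGENOUS_CONTROLS + EXTERNAL_CONTROLS


@dataclass(frozen=True)
class Amplicon:
    gene: str
    length: int  # expected fragment size, bp
    panel: int  # panel number (1-based)
    is_control: bool = False


@dataclass
class PanelDefinition:
    """Marker amplicons grouped into multiplex panels, plus controls."""

    amplicons: list[Amplicon]

    def panel_ids(self) -> list[int]:
        return sorted({a.panel for a in self.amplicons})

    def in_panel(self, panel: int) -> list[Amplicon]:
        return [a for a in self.amplicons if a.panel == panel]

    def marker_amplicons(self) -> list[Amplicon]:
        return [a for a in self.amplicons if not a.is_control]

    def marker_genes(self) -> set[str]:
        return {a.gene for a in self.marker_amplicons()}

    def min_spacing(self) -> int:
        """Smallest within-panel gap between expected fragment lengths."""
        gaps = []
        for pid in self.panel_ids():
            lengths = sorted(a.length for a in self.in_panel(pid))
            gaps.extend(b - a for a, b in zip(lengths, lengths[1:]))
        return min(gaps) if gaps else 0


@dataclass
class PeakTable:
    """Electropherogram peaks for one sample x panel run."""

    sample_id: str
    panel_id: int
    peaks: list[tuple[float, float]]  # (fragment size bp, peak area)

    def __post_init__(self) -> None:
        for size, area in self.peaks:
            if size <= 0:
                raise ValidationError(
                    f"non-positive fragment size {size!r} in sample "
                    f"{self.sample_id!r} panel {self.panel_id}"
                )
            if area < 0:
                raise ValidationError(
                    f"negative peak area {area!r} in sample "
                    f"{self.sample_id!r} panel {self.panel_id}"
                )


# ---------------------------------------------------------------------------
# panel validation


def validate_panel(
    p: PanelDefinition, expected_genes: MarkerPanel | Iterable[str] | None = None
) -> list[str]:
    """Check a panel design against the assay's printed rules.

    Returns a list of human-readable violation strings (prefixed with a rule
    tag); an empty list means the panel is valid.  Violations are report
    content, not exceptions.
    """
    violations: list[str] = []
    for a in p.marker_amplicons():
        if not (LENGTH_MIN <= a.length <= LENGTH_MAX):
            violations.append(
                f"range: amplicon {a.gene!r} (panel {a.panel}) length "
                f"{a.length} bp outside [{LENGTH_MIN}, {LENGTH_MAX}] bp"
            )
    for pid in p.panel_ids():
        amps = sorted(p.in_panel(pid), key=lambda a: a.length)
        for a, b in zip(amps, amps[1:]):
            if b.length - a.length < MIN_SPACING:
                violations.append(
                    f"spacing: panel {pid} amplicons {a.gene!r} ({a.length} bp) "
                    f"and {b.gene!r} ({b.length} bp) are {b.length - a.length} bp "
                    f"apart (< {MIN_SPACING} bp)"
                )
        controls = {a.gene for a in amps if a.is_control}
        for c in ALL_CONTROLS:
            if c not in controls:
                violations.append(f"controls: panel {pid} lacks reference control {c!r}")
    if expected_genes is not None:
        expected = set(expected_genes)
        got = p.marker_genes()
        if got != expected:
            violations.append(
                f"coverage: marker genes differ from the {len(expected)}-gene set; "
                f"missing {sorted(expected - got)}, unexpected {sorted(got - expected)}"
            )
    return violations


# ---------------------------------------------------------------------------
# peak assignment


def assign_peaks(
    pt: PeakTable, p: PanelDefinition, tolerance_bp: float = 1.5
) -> tuple[dict[str, float], list[tuple[float, float]]]:
    """Match peaks to this panel's amplicons by nearest expected length.

    Returns ``(gene_areas, artifacts)``: areas per gene of the panel
    (controls included; genes with no matched peak get 0.0; a gene assayed
    by several amplicons in the panel gets their mean), plus the list of
    peaks that matched nothing within the tolerance.  Two peaks landing on
    the same amplicon raise :class:`AmbiguousPeakError`.
    """
    amps = p.in_panel(pt.panel_id)
    if not amps:
        raise ValidationError(f"panel {pt.panel_id} not present in panel definition")
    lengths = np.array([a.length for a in amps], dtype=float)
    matched: dict[int, float] = {}
    artifacts: list[tuple[float, float]] = []
    for size, area in pt.peaks:
        dists = np.abs(lengths - size)
        idx = int(np.argmin(dists))
        if dists[idx] <= tolerance_bp:
            if idx in matched:
                raise AmbiguousPeakError(
                    f"sample {pt.sample_id!r} panel {pt.panel_id}: two peaks match "
                    f"amplicon {amps[idx].gene!r} at {amps[idx].length} bp"
                )
            matched[idx] = float(area)
        else:
            artifacts.append((float(size), float(area)))
    per_gene: dict[str, list[float]] = {}
    for i, a in enumerate(amps):
        per_gene.setdefault(a.gene, []).append(matched.get(i, 0.0))
    gene_areas = {g: float(np.mean(v)) for g, v in per_gene.items()}
    return gene_areas, artifacts


def peaks_to_matrix(
    tables: Sequence[PeakTable],
    p: PanelDefinition,
    panel: MarkerPanel,
    tolerance_bp: float = 1.5,
) -> ExpressionMatrix:
    """Assemble per-sample peak tables from all panels into an
    ExpressionMatrix over the marker genes (controls dropped, duplicate
    amplicons averaged), tagged platform "AFA"."""
    by_sample: dict[str, dict[str, list[float]]] = {}
    for pt in tables:
        areas, _ = assign_peaks(pt, p, tolerance_bp)
        acc = by_sample.setdefault(pt.sample_id, {})
        for g, v in areas.items():
            if g in ALL_CONTROLS:
                continue
            acc.setdefault(g, []).append(v)
    sample_ids = list(by_sample)
    data = np.zeros((len(panel.genes), len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        areas = by_sample[sid]
        missing = [g for g in panel.genes if g not in areas]
        if missing:
            raise ValidationError(
                f"sample {sid!r}: no peak table covers marker genes {missing}"
            )
        for i, g in enumerate(panel.genes):
            data[i, j] = float(np.mean(areas[g]))
    frame = pd.DataFrame(data, index=list(panel.genes), columns=sample_ids)
    return ExpressionMatrix(frame, platform="AFA")


# ---------------------------------------------------------------------------
# reference-control QC


@dataclass
class QCVerdict:
    sample_id: str
    flags: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.flags


def qc_controls(
    areas: Mapping[str, float],
    p: PanelDefinition,
    min_endogenous: float = 1.0,
    sample_id: str = "",
) -> QCVerdict:
    """Apply the reference controls' monitoring semantics.

    KanR is spiked before reverse transcription, so a missing KanR peak
    means the RT or PCR step failed.  pcDNA3.1(+) enters at the PCR step
    only; its absence while KanR amplified marks a PCR anomaly.  Endogenous
    references below ``min_endogenous`` flag low RNA input.
    """
    flags: list[str] = []
    kan = float(areas.get("KanR", 0.0))
    pcdna = float(areas.get("pcDNA3.1(+)", 0.0))
    if kan <= 0:
        flags.append("RT/PCR failure: KanR control absent")
    elif pcdna <= 0:
        flags.append("PCR anomaly: pcDNA3.1(+) absent while KanR amplified")
    for g in ENDOGENOUS_CONTROLS:
        if float(areas.get(g, 0.0)) < min_endogenous:
            flags.append(f"low input: endogenous reference {g} below {min_endogenous}")
    return QCVerdict(sample_id=sample_id, flags=flags)


# ---------------------------------------------------------------------------
# standard-curve quantification


@dataclass
class StandardCurve:
    """Log–log linear calibration: log10(area) = intercept + slope·log10(qty).

    Fitted by least squares from >=2 calibration points with distinct input
    quantities; the curve must be strictly increasing (slope > 0).
    """

    points: list[tuple[float, float]]  # (known input quantity, peak area)
    slope: float = field(init=False)
    intercept: float = field(init=False)

    def __post_init__(self) -> None:
        qty = [q for q, _ in self.points]
        if len(self.points) < 2 or len(set(qty)) < 2:
            raise ValidationError(
                "standard curve needs >=2 calibration points with distinct inputs"
            )
        if any(q <= 0 or a <= 0 for q, a in self.points):
            raise ValidationError("calibration quantities and areas must be positive")
        lq = np.log10([q for q, _ in self.points])
        la = np.log10([a for _, a in self.points])
        slope, intercept = np.polyfit(lq, la, 1)
        if slope <= 0:
            raise ValidationError(
                f"fitted standard curve is not increasing (slope {slope:.4g})"
            )
        object.__setattr__(self, "slope", float(slope))
        object.__setattr__(self, "intercept", float(intercept))

    def quantity(self, area: float) -> float:
        """Invert the curve: peak area -> input quantity.  Zero area maps to
        zero quantity (undetected); areas outside the calibrated range are
        extrapolated with a warning."""
        if area < 0:
            raise ValidationError(f"negative peak area {area!r}")
        if area == 0:
            return 0.0
        areas = [a for _, a in self.points]
        if not (min(areas) <= area <= max(areas)):
            warnings.warn(
                f"peak area {area:.4g} outside calibrated range "
                f"[{min(areas):.4g}, {max(areas):.4g}]; extrapolating",
                stacklevel=2,
            )
        return float(10 ** ((math.log10(area) - self.intercept) / self.slope))


def identity_curve() -> StandardCurve:
    """y = x calibration (slope 1, intercept 0 in log–log space)."""
    return StandardCurve([(1.0, 1.0), (10.0, 10.0)])


def quantify(
    areas: Mapping[str, float],
    curves: StandardCurve | Mapping[str, StandardCurve],
    reference: Sequence[str] = ENDOGENOUS_CONTROLS,
) -> dict[str, float]:
    """Standard-curve quantification with endogenous-reference normalization.

    Each gene's area is inverted through its curve (a single curve may be
    shared by all genes), then divided by the geometric mean of the three
    endogenous reference quantities.  Zero areas pass through as zero so the
    downstream rank transform sees them as undetected.  A reference with
    area 0 makes the whole sample unquantifiable.
    """

    def curve_for(g: str) -> StandardCurve:
        if isinstance(curves, StandardCurve):
            return curves
        try:
            return curves[g]
        except KeyError:
            raise QuantificationError(f"no standard curve for gene {g!r}") from None

    ref_q = []
    for r in reference:
        a = float(areas.get(r, 0.0))
        if a <= 0:
            raise QuantificationError(
                f"endogenous reference {r!r} has zero area; sample cannot be quantified"
            )
        ref_q.append(curve_for(r).quantity(a))
    norm = float(np.exp(np.mean(np.log(ref_q))))
    out: dict[str, float] = {}
    for g, a in areas.items():
        if g in reference:
            continue
        out[g] = curve_for(g).quantity(float(a)) / norm
    return out


# ---------------------------------------------------------------------------
# default (synthetic) panel and panel file I/O


def default_panel() -> tuple[PanelDefinition, MarkerPanel]:
    """Synthetic, rule-conforming default panel.

    The assay's real amplicon table is proprietary to the published kit, so
    this fixture is synthetic: 57 marker genes assayed by 58 amplicons
    (PBX1 twice) in 3 panels of 20/19/19 amplicons, marker lengths starting
    at 140 bp with 6 bp spacing (within 137–316 bp), and the five reference
    controls at 280–304 bp in every panel.  It satisfies every design rule
    checked by :func:`validate_panel`.
    """
    genes = ["PBX1"] + [f"MKG{i:02d}" for i in range(1, 57)]
    amplicon_genes = ["PBX1", "PBX1"] + genes[1:]  # 58 amplicons
    sizes = (20, 19, 19)
    amplicons: list[Amplicon] = []
    k = 0
    control_lengths = dict(zip(ALL_CONTROLS, (280, 286, 292, 298, 304)))
    for pid, size in enumerate(sizes, start=1):
        for slot in range(size):
            amplicons.append(
                Amplicon(gene=amplicon_genes[k], length=140 + 6 * slot, panel=pid)
            )
            k += 1
        for c, ln in control_lengths.items():
            amplicons.append(Amplicon(gene=c, length=ln, panel=pid, is_control=True))
    return PanelDefinition(amplicons), MarkerPanel(tuple(genes))


def read_panel(path: str | Path) -> PanelDefinition:
    """Read a panel CSV with columns gene,panel,length,is_control."""
    df = pd.read_csv(path)
    required = {"gene", "panel", "length", "is_control"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"panel file {path} must have columns {sorted(required)}"
        )
    amplicons = [
        Amplicon(
            gene=str(r.gene),
            length=int(r.length),
            panel=int(r.panel),
            is_control=bool(r.is_control),
        )
        for r in df.itertuples(index=False)
    ]
    return PanelDefinition(amplicons)


def write_panel(p: PanelDefinition, path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": a.gene, "panel": a.panel, "length": a.length, "is_control": a.is_control}
            for a in p.amplicons
        ]
    ).to_csv(path, index=False)
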