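"""Study design constants for the goldfish diel expression study.

The study sampled goldfish (*Carassius auratus*) every 4 h across one full
24-h light/dark cycle (12L:12D, lights on at ZT-0, scheduled feeding at
ZT-4), six fish per sampling time, and measured *preproghrelin* and *ghs-r1*
mRNA by RT-qPCR in five tissues.  The published single-component cosinor
parameters (mesor, amplitude, acrophase) for the five tissue x gene panels
with a significant 24-h rhythm are collected here; they serve as the
generative ground truth for the synthetic datasets that stand in for the
raw per-fish measurements, which were never deposited.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Sampling times in hours after lights-on.  ZT-24 is a distinct sampling
#: group (seven groups), even though its cosinor regressors coincide with
#: ZT-0 by 24-h periodicity.
TIMEPOINTS_H: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0)

#: Fish sampled per time point.
N_PER_TIMEPOINT: int = 6

#: Photoperiod annotations (hours on the ZT scale).
LIGHTS_ON_ZT: float = 0.0
DARK_ONSET_ZT: float = 12.0
FEEDING_ZT: float = 4.0

#: Reference genes used for qPCR normalization.
REFERENCE_GENES: tuple[str, ...] = ("beta-actin", "ef1a", "18s")

TARGET_GENES: tuple[str, ...] = ("preproghrelin", "ghs-r1")

TISSUES: tuple[str, ...] = (
    "forebrain",
    "hypothalamus",
    "hindbrain",
    "pituitary",
    "gastrointestinal_tract",
)


@dataclass(frozen=True)
class SeriesParams:
    """Generative cosinor parameters for one tissue x gene expression series.

    ``mesor`` and ``amplitude`` are in relative-expression units;
    ``acrophase_h`` is the clock time of peak expression in hours on the
    ZT scale, in ``[0, 24)``.  A flat (arrhythmic) series has
    ``amplitude == 0``; its acrophase is then irrelevant.
    """

    tissue: str
    gene: str
    mesor: float
    amplitude: float
    acrophase_h: float = 0.0

    def __post_init__(self) -> None:
        if self.mesor <= 0:
            raise ValueError(f"mesor must be > 0, got {self.mesor}")
        if self.amplitude < 0:
            raise ValueError(f"amplitude must be >= 0, got {self.amplitude}")
        if not 0.0 <= self.acrophase_h < 24.0:
            raise ValueError(
                f"acrophase_h must lie in [0, 24), got {self.acrophase_h}"
            )


#: Published rhythm parameters (mesor, amplitude, acrophase in ZT hours)
#: for the five panels where the study detected a significant 24-h rhythm.
RHYTHMIC_PANEL: tuple[SeriesParams, ...] = (
    SeriesParams("hypothalamus", "preproghrelin", 2.7, 1.2, 16.3),
    SeriesParams("pituitary", "preproghrelin", 2.2, 1.0, 20.0),
    SeriesParams("gastrointestinal_tract", "preproghrelin", 3.9, 3.3, 17.4),
    SeriesParams("hypothalamus", "ghs-r1", 1.5, 0.9, 16.9),
    SeriesParams("pituitary", "ghs-r1", 2.7, 1.4, 19.4),
)

#: Panels where no significant daily variation was found are simulated flat.
#: Their mesors are not published; 1.5 relative-expression units is a level
#: comparable to the rhythmic panels' troughs.
FLAT_PANEL: tuple[SeriesParams, ...] = (
    SeriesParams("forebrain", "preproghrelin", 1.5, 0.0),
    SeriesParams("hindbrain", "preproghrelin", 1.5, 0.0),
    SeriesParams("forebrain", "ghs-r1", 1.5, 0.0),
    SeriesParams("hindbrain", "ghs-r1", 1.5, 0.0),
    SeriesParams("gastrointestinal_tract", "ghs-r1", 1.5, 0.0),
)

#: Full 5 tissue x 2 gene study panel.
STUDY_PANEL: tuple[SeriesParams, ...] = RHYTHMIC_PANEL + FLAT_PANEL

#: Default per-fish noise standard deviation, relative-expression units.
DEFAULT_NOISE_SD: float = 1.0

#: Significance thresholds of the dual rhythm-detection criterion.
ALPHA_ANOVA: float = 0.05
ALPHA_COSINOR: float = 0.005

#: Confidence level for the reported amplitude interval.
AMPLITUDE_CI_LEVEL: float = 0.99
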