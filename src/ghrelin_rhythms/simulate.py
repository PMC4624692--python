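"""Synthetic per-fish expression and raw-Ct datasets.

Each tissue x gene series follows the single-component 24-h cosinor mean

    f(t) = M + A * cos(t * pi/12 - phi),

with ``t`` in ZT hours and ``phi = acrophase_h * pi/12``; per-fish scatter
is added either on the relative-expression scale (additive Gaussian, the
default, matching how the study displays mean +/- SEM) or multiplicatively
(lognormal, for strictly positive values).  Raw Ct tables are generated by
inverting the 2^-ddCt transform so the quantification stage can be
round-trip tested.

Randomness: one master seed; each series draws from its own child stream
derived deterministically from (seed, tissue, gene), so a series'
values do not depend on which other series share the panel.
"""

from __future__ import annotations

import dataclasses
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_NOISE_SD,
    N_PER_TIMEPOINT,
    TIMEPOINTS_H,
    SeriesParams,
)

#: Angular frequency of the fixed 24-h period, rad/h.
OMEGA: float = np.pi / 12.0

#: Additive-mode simulated expression values are clipped at this floor so
#: the Ct back-transform log2(expression) stays defined.
EXPRESSION_FLOOR: float = 1e-6

EXPRESSION_COLUMNS = ["sample_id", "tissue", "gene", "zt_h", "rq", "floored"]
CT_COLUMNS = ["sample_id", "tissue", "gene", "is_reference", "zt_h", "replicate", "ct"]


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Design and noise model for one simulated study.

    Parameters
    ----------
    series
        Generative cosinor parameters, one entry per tissue x gene panel.
    timepoints_h
        Sampling times in ZT hours, strictly increasing within [0, 24].
    n_per_timepoint
        Fish sampled per time point.
    noise_sd
        Additive mode: SD of Gaussian noise in relative-expression units.
        Lognormal mode: SD of the Gaussian on the natural-log scale.
    noise_scale
        ``"additive"`` or ``"lognormal"``.
    ct_baseline
        Cycles; target Ct is simulated as ``ct_baseline - log2(expression)``.
    ref_gene_ct
        Cycles; the reference gene's Ct, constant across samples up to
        ``ref_ct_noise_sd``.
    ref_gene_name
        Gene label used for simulated reference-gene wells.
    ref_ct_noise_sd
        Optional Gaussian jitter (cycles) on reference Ct values.
    seed
        Non-negative master seed.
    """

    series: tuple[SeriesParams, ...]
    timepoints_h: tuple[float, ...] = TIMEPOINTS_H
    n_per_timepoint: int = N_PER_TIMEPOINT
    noise_sd: float = DEFAULT_NOISE_SD
    noise_scale: str = "additive"
    ct_baseline: float = 24.0
    ref_gene_ct: float = 18.0
    ref_gene_name: str = "ref_gene"
    ref_ct_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.series:
            raise ConfigError("series must contain at least one entry")
        keys = [(s.tissue, s.gene) for s in self.series]
        if len(set(keys)) != len(keys):
            raise ConfigError("duplicate (tissue, gene) entries in series")
        tp = tuple(float(t) for t in self.timepoints_h)
        if len(tp) < 1 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ConfigError("timepoints_h must be strictly increasing")
        if tp[0] < 0.0 or tp[-1] > 24.0:
            raise ConfigError("timepoints_h must lie in [0, 24]")
        object.__setattr__(self, "timepoints_h", tp)
        if self.n_per_timepoint < 1:
            raise ConfigError("n_per_timepoint must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.noise_scale not in ("additive", "lognormal"):
            raise ConfigError(
                f"noise_scale must be 'additive' or 'lognormal', got {self.noise_scale!r}"
            )
        if self.ref_ct_noise_sd < 0:
            raise ConfigError("ref_ct_noise_sd must be >= 0")
        if not 0 <= int(self.seed) < 2**31:
            raise ConfigError("seed must be a non-negative integer < 2**31")


def cosinor_mean(
    t: np.ndarray | float, mesor: float, amplitude: float, acrophase_h: float
) -> np.ndarray | float:
    """Deterministic cosinor mean M + A*cos(t*pi/12 - phi) at ZT hours ``t``."""
    return mesor + amplitude * np.cos(OMEGA * np.asarray(t, dtype=float) - OMEGA * acrophase_h)


def _series_rng(seed: int, tissue: str, gene: str) -> np.random.Generator:
    # Child stream keyed by (seed, tissue, gene): stable across panel composition.
    key = [int(seed), zlib.crc32(tissue.encode()), zlib.crc32(gene.encode())]
    return np.random.default_rng(np.random.SeedSequence(key))


def _sample_id(tissue: str, zt: float, fish: int) -> str:
    return f"{tissue}_ZT{zt:g}_f{fish:02d}"


def simulate_expression(config: SimulationConfig) -> pd.DataFrame:
    """Simulate per-fish relative expression for every series in ``config``.

    Returns a long-format frame with one row per fish per series, columns
    ``sample_id, tissue, gene, zt_h, rq, floored``.  ``floored`` marks
    additive-mode values clipped at the positivity floor.
    """
    frames = []
    tps = np.asarray(config.timepoints_h, dtype=float)
    n = config.n_per_timepoint
    for s in config.series:
        rng = _series_rng(config.seed, s.tissue, s.gene)
        mean = cosinor_mean(tps, s.mesor, s.amplitude, s.acrophase_h)
        mean_mat = np.repeat(mean, n)  # one row block per timepoint
        if config.noise_scale == "additive":
            values = mean_mat + rng.normal(0.0, config.noise_sd, size=mean_mat.shape)
            floored = values < EXPRESSION_FLOOR
            values = np.where(floored, EXPRESSION_FLOOR, values)
        else:
            values = mean_mat * np.exp(rng.normal(0.0, config.noise_sd, size=mean_mat.shape))
            floored = np.zeros(values.shape, dtype=bool)
        zt = np.repeat(tps, n)
        fish = np.tile(np.arange(1, n + 1), tps.size)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": [_sample_id(s.tissue, z, f) for z, f in zip(zt, fish)],
                    "tissue": s.tissue,
                    "gene": s.gene,
                    "zt_h": zt,
                    "rq": values,
                    "floored": floored,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_ct(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a raw Ct table whose 2^-ddCt quantification recovers the
    simulated expression profile up to the calibrator scaling.

    Target wells carry ``ct = ct_baseline - log2(expression)``; every sample
    additionally carries one reference-gene well at ``ref_gene_ct`` (plus
    optional jitter).  Returns columns
    ``sample_id, tissue, gene, is_reference, zt_h, replicate, ct``.
    """
    expr = simulate_expression(config)
    target = pd.DataFrame(
        {
            "sample_id": expr["sample_id"],
            "tissue": expr["tissue"],
            "gene": expr["gene"],
            "is_reference": False,
            "zt_h": expr["zt_h"],
            "replicate": 1,
            "ct": config.ct_baseline - np.log2(expr["rq"].to_numpy()),
        }
    )
    samples = expr[["sample_id", "tissue", "zt_h"]].drop_duplicates(ignore_index=True)
    ref_ct = np.full(len(samples), config.ref_gene_ct, dtype=float)
    if config.ref_ct_noise_sd > 0:
        rng = _series_rng(config.seed, "__reference__", config.ref_gene_name)
        ref_ct = ref_ct + rng.normal(0.0, config.ref_ct_noise_sd, size=ref_ct.shape)
    reference = pd.DataFrame(
        {
            "sample_id": samples["sample_id"],
            "tissue": samples["tissue"],
            "gene": config.ref_gene_name,
            "is_reference": True,
            "zt_h": samples["zt_h"],
            "replicate": 1,
            "ct": ref_ct,
        }
    )
    return pd.concat([target, reference], ignore_index=True)[CT_COLUMNS]


def simulate_null(config: SimulationConfig) -> pd.DataFrame:
    """Simulate an arrhythmic study: every series' amplitude forced to zero.

    Record-for-record identical to ``simulate_expression`` on the same
    config with all amplitudes set to 0 (noise streams are unchanged).
    """
    flat = tuple(dataclasses.replace(s, amplitude=0.0) for s in config.series)
    return simulate_expression(dataclasses.replace(config, series=flat))
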