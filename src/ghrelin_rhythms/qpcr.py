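"""Relative qPCR quantification by the 2^-ddCt method.

Per sample: dCt = Ct_target - Ct_reference, with the reference Ct taken as
the arithmetic mean of the configured reference genes' Cts (equivalent to
normalizing by the geometric mean of their expression levels).  Per
tissue x gene panel, per-sample relative expression 2^-dCt is divided by
the group mean of the lowest-expression sampling time, so that calibrator
group's mean relative expression is exactly 1 — the study's stated
normalization.  Amplification efficiency is assumed to be 100%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class QuantError(ValueError):
    """Invalid input to the relative-quantification stage."""


@dataclass(frozen=True)
class QuantConfig:
    """Reference-gene handling and calibrator choice.

    ``ref_aggregation`` is ``"geometric_mean_expression"`` (arithmetic mean
    of the reference Cts; the multi-reference default) or ``"single"``
    (exactly one reference gene, passed through).  ``calibrator_rule`` is
    ``"lowest_group_mean"`` (default: the sampling time whose group-mean
    expression is lowest, per panel) or ``"explicit_group"`` with
    ``calibrator_zt`` naming the sampling time.
    """

    reference_genes: tuple[str, ...]
    ref_aggregation: str = "geometric_mean_expression"
    calibrator_rule: str = "lowest_group_mean"
    calibrator_zt: float | None = None

    def __post_init__(self) -> None:
        if not self.reference_genes:
            raise QuantError("at least one reference gene is required")
        if self.ref_aggregation not in ("geometric_mean_expression", "single"):
            raise QuantError(f"unknown ref_aggregation {self.ref_aggregation!r}")
        if self.ref_aggregation == "single" and len(self.reference_genes) != 1:
            raise QuantError("ref_aggregation 'single' requires exactly one reference gene")
        if self.calibrator_rule not in ("lowest_group_mean", "explicit_group"):
            raise QuantError(f"unknown calibrator_rule {self.calibrator_rule!r}")
        if self.calibrator_rule == "explicit_group" and self.calibrator_zt is None:
            raise QuantError("calibrator_rule 'explicit_group' requires calibrator_zt")


@dataclass
class RelativeExpressionTable:
    """Per-fish relative expression with calibration provenance.

    ``records`` is a long-format frame (sample_id, tissue, gene, zt_h, rq);
    ``calibrators`` maps (tissue, gene) to the sampling time assigned
    relative expression 1; ``calibration_log`` records the calibrator
    group's mean dCt per panel.
    """

    records: pd.DataFrame
    calibrators: dict[tuple[str, str], float] = field(default_factory=dict)
    calibration_log: pd.DataFrame | None = None
    method: str = ""


def _mean_technical_replicates(cts: pd.DataFrame) -> pd.DataFrame:
    """Average duplicated qPCR wells at the Ct level."""
    keys = ["sample_id", "tissue", "gene", "is_reference", "zt_h"]
    return cts.groupby(keys, as_index=False, sort=False)["ct"].mean()


def aggregate_reference(cts: pd.DataFrame, config: QuantConfig) -> pd.Series:
    """Per-sample reference Ct, indexed by sample_id.

    Arithmetic mean of the configured reference genes' Ct values; single-gene
    mode passes the one reference through.  Raises :class:`QuantError`
    naming any sample missing a configured reference gene.
    """
    ref = cts[cts["gene"].isin(config.reference_genes)]
    ref = _mean_technical_replicates(ref)
    counts = ref.groupby("sample_id")["gene"].nunique()
    all_samples = pd.Index(cts["sample_id"].unique())
    missing = [
        s
        for s in all_samples
        if counts.get(s, 0) < len(config.reference_genes)
    ]
    if missing:
        raise QuantError(
            "samples missing a Ct for a configured reference gene: "
            + ", ".join(map(str, missing[:10]))
            + ("..." if len(missing) > 10 else "")
        )
    return ref.groupby("sample_id")["ct"].mean()


def relative_expression(cts: pd.DataFrame, config: QuantConfig) -> RelativeExpressionTable:
    """Compute 2^-ddCt relative expression from a raw Ct table.

    The input is a long-format frame with columns
    ``sample_id, tissue, gene, is_reference, zt_h, ct`` (``replicate``
    optional; technical replicates are averaged at the Ct level).  Each
    tissue x gene panel is calibrated so that the sampling time with the
    lowest group-mean expression has mean relative expression exactly 1;
    ties in the lowest group mean resolve to the earliest ZT.
    """
    required = {"sample_id", "tissue", "gene", "is_reference", "zt_h", "ct"}
    missing_cols = required - set(cts.columns)
    if missing_cols:
        raise QuantError(f"Ct table missing columns: {sorted(missing_cols)}")
    if cts.empty:
        raise QuantError("Ct table is empty")
    if "replicate" not in cts.columns:
        dup = cts.duplicated(subset=["sample_id", "gene"], keep=False)
        if dup.any():
            raise QuantError(
                "duplicated (sample_id, gene) wells without a replicate index; "
                "add a 'replicate' column"
            )

    is_ref = cts["is_reference"].astype(bool) | cts["gene"].isin(config.reference_genes)
    ref_ct = aggregate_reference(cts[is_ref], config) if is_ref.any() else None
    if ref_ct is None:
        raise QuantError("no reference-gene wells found")

    targets = _mean_technical_replicates(cts[~is_ref])
    if targets.empty:
        raise QuantError("no target-gene wells found")
    targets = targets.merge(
        ref_ct.rename("ref_ct"), left_on="sample_id", right_index=True, how="left"
    )
    if targets["ref_ct"].isna().any():
        bad = targets.loc[targets["ref_ct"].isna(), "sample_id"].unique()
        raise QuantError(f"samples without reference Ct: {list(bad[:10])}")
    targets["delta_ct"] = targets["ct"] - targets["ref_ct"]
    # Relative to the reference gene(s), before calibration.
    targets["rel"] = np.exp2(-targets["delta_ct"])

    out_frames = []
    calibrators: dict[tuple[str, str], float] = {}
    log_rows = []
    for (tissue, gene), panel in targets.groupby(["tissue", "gene"], sort=True):
        group_mean = panel.groupby("zt_h")["rel"].mean()
        if (panel.groupby("zt_h").size() < 1).any() or group_mean.empty:
            raise QuantError(f"empty sampling-time groups in panel ({tissue}, {gene})")
        if config.calibrator_rule == "explicit_group":
            cal_zt = float(config.calibrator_zt)  # type: ignore[arg-type]
            if cal_zt not in group_mean.index:
                raise QuantError(
                    f"explicit calibrator ZT {cal_zt} absent from panel ({tissue}, {gene})"
                )
        else:
            lowest = group_mean[group_mean == group_mean.min()]
            cal_zt = float(min(lowest.index))  # ties -> earliest ZT
        scale = group_mean.loc[cal_zt]
        panel = panel.copy()
        panel["rq"] = panel["rel"] / scale
        calibrators[(tissue, gene)] = cal_zt
        mean_dct = panel.loc[panel["zt_h"] == cal_zt, "delta_ct"].mean()
        log_rows.append(
            {"tissue": tissue, "gene": gene, "calibrator_zt": cal_zt, "calibrator_mean_delta_ct": mean_dct}
        )
        logger.info(
            "calibrator for (%s, %s): ZT-%g (mean dCt %.3f)", tissue, gene, cal_zt, mean_dct
        )
        out_frames.append(panel[["sample_id", "tissue", "gene", "zt_h", "rq"]])

    records = pd.concat(out_frames, ignore_index=True)
    return RelativeExpressionTable(
        records=records,
        calibrators=calibrators,
        calibration_log=pd.DataFrame(log_rows),
        method=(
            "2^-ddCt; reference aggregation: arithmetic mean of reference Cts; "
            "calibrator: lowest group-mean expression per (tissue, gene)"
        ),
    )
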