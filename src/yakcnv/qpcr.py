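"""Copy-number quantification from qPCR Ct values (ddCT method).

For each sample x target region: dCt = mean(target Ct) - mean(reference Ct)
over technical replicates; ddCt subtracts the mean dCt of calibrator
samples (assumed diploid at the target); relative quantity = 2^(-ddCt);
copy number = 2 x relative quantity.  Concordance against sequencing-derived
copy numbers is reported both as direction agreement (gain/loss/neutral
relative to 2) and as exact rounded-integer agreement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from ._util import round_half_away

REQUIRED_COLUMNS = [
    "sample_id",
    "target_region_id",
    "replicate_index",
    "target_ct",
    "reference_ct",
]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    target_region_id: str
    mean_delta_ct: float
    delta_delta_ct: float

    @property
    def relative_quantity(self) -> float:
        return 2.0 ** (-self.delta_delta_ct)

    @property
    def copy_number(self) -> float:
        return 2.0 * self.relative_quantity

    @property
    def rounded_cn(self) -> int:
        return max(0, round_half_away(self.copy_number))


def _direction(cn: float) -> str:
    if cn > 2:
        return "gain"
    if cn < 2:
        return "loss"
    return "neutral"


def delta_delta_ct(
    table: pd.DataFrame, calibrator_samples: Iterable[str]
) -> list[CopyNumberEstimate]:
    """ddCT copy-number estimates for every (sample, target) in the table.

    ``table`` columns: sample_id, target_region_id, replicate_index,
    target_ct, reference_ct.  Calibrators are assumed diploid at every
    target; their mean dCt anchors ddCt = 0 <=> CN 2.  Missing replicates
    trigger a warning and the available ones are averaged; a target with no
    calibrator rows is an error.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table lacks columns: {missing}")
    calibrators = set(calibrator_samples)
    if not calibrators:
        raise ValueError("at least one calibrator sample is required")

    grouped = table.groupby(["sample_id", "target_region_id"], sort=True)
    dct: dict[tuple[str, str], float] = {}
    for (sample, target), sub in grouped:
        if len(sub) != 3:
            warnings.warn(
                f"{sample}/{target}: {len(sub)} replicates (expected 3); "
                "averaging available wells",
                stacklevel=2,
            )
        dct[(sample, target)] = float(
            sub["target_ct"].mean() - sub["reference_ct"].mean()
        )

    targets = sorted({t for _, t in dct})
    cal_mean: dict[str, float] = {}
    for target in targets:
        vals = [v for (s, t), v in dct.items() if t == target and s in calibrators]
        if not vals:
            raise ValueError(f"target {target}: no calibrator sample in table")
        cal_mean[target] = sum(vals) / len(vals)

    return [
        CopyNumberEstimate(
            sample_id=sample,
            target_region_id=target,
            mean_delta_ct=v,
            delta_delta_ct=v - cal_mean[target],
        )
        for (sample, target), v in sorted(dct.items())
    ]


def concordance(
    estimates: Iterable[CopyNumberEstimate],
    sequencing_cns: Mapping[tuple[str, str], int],
) -> dict[str, object]:
    """Agreement between qPCR and sequencing copy numbers.

    Keys of ``sequencing_cns`` are (sample_id, target_region_id).  Pairs
    present in both inputs are scored; unmatched keys on either side are
    returned for inspection.  Raises if no pair matches (nothing was
    validated).
    """
    est = {(e.sample_id, e.target_region_id): e for e in estimates}
    common = sorted(est.keys() & sequencing_cns.keys())
    if not common:
        raise ValueError("no (sample, target) pair shared between qPCR and sequencing")

    n_dir = sum(
        _direction(est[k].rounded_cn) == _direction(sequencing_cns[k]) for k in common
    )
    n_exact = sum(est[k].rounded_cn == sequencing_cns[k] for k in common)
    return {
        "n_pairs": len(common),
        "n_direction_concordant": n_dir,
        "n_exact_concordant": n_exact,
        "fraction_direction": n_dir / len(common),
        "fraction_exact": n_exact / len(common),
        "unmatched_qpcr": sorted(est.keys() - sequencing_cns.keys()),
        "unmatched_sequencing": sorted(sequencing_cns.keys() - est.keys()),
    }


def estimates_table(estimates: Iterable[CopyNumberEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sample_id": e.sample_id,
                "target_region_id": e.target_region_id,
                "mean_delta_ct": e.mean_delta_ct,
                "delta_delta_ct": e.delta_delta_ct,
                "relative_quantity": e.relative_quantity,
                "copy_number": e.copy_number,
                "rounded_cn": e.rounded_cn,
            }
            for e in estimates
        ]
    )
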