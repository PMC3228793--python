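"""Paired-pulse plasticity statistics over release records.

Each pair of consecutive spikes is scored by its paired-pulse ratio
PPR = RR2/RR1 and labelled:

* PPD      — PPR < 1 (and, by convention, PPR exactly 1);
* PPF      — PPR > 1 with a non-decreasing utilization (du >= 0): genuine
  residual-Ca2+ facilitation;
* RECOVERY — PPR > 1 despite du < 0, driven by resource reintegration
  (dx > 0): recovery from depression, reported as its own class.

For Poisson drive "pairs" are all consecutive spike pairs (sliding window).
The headline PPF/PPD ratio excludes RECOVERY pairs by default; a switch
folds them into PPF.  Pairs with RR1 = 0 are excluded from labelling and
counted separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .astrocyte import AstroParams, simulate_coupled
from .stimulus import GRESchedule, SpikeTrain, gen_poisson_train
from .synapse import ReleaseRecord, SynapseParams, simulate_train

__all__ = [
    "PairClassification",
    "TrialSummary",
    "classify_pairs",
    "mean_ppr",
    "run_trial_ensemble",
    "sweep_gre_frequency",
]

PPF, PPD, RECOVERY, UNDEFINED = "PPF", "PPD", "RECOVERY", "UNDEFINED"


@dataclass(frozen=True)
class PairClassification:
    pair_index: int
    t1: float
    t2: float
    rr1: float
    rr2: float
    ppr: float
    delta_u: float
    delta_x: float
    label: str


@dataclass(frozen=True)
class TrialSummary:
    """Across-trial aggregation of per-trial pair counts.

    ``ratio_ppf_ppd`` statistics are over per-trial PPF/PPD ratios (trials
    with zero PPD pairs are skipped and counted in ``n_ratio_trials``);
    ``pooled_ratio`` divides the summed counts and is always defined unless
    no pair depressed in any trial.  SD fields are None for a single trial.
    """

    n_trials: int
    mean_ppf: float
    sd_ppf: float | None
    mean_ppd: float
    sd_ppd: float | None
    mean_recovery: float
    sd_recovery: float | None
    ratio_ppf_ppd: float
    sd_ratio: float | None
    n_ratio_trials: int
    pooled_ratio: float
    n_undefined: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def classify_pairs(
    records: Sequence[ReleaseRecord], tie_label: str = PPD
) -> list[PairClassification]:
    """Label every consecutive release pair; fewer than 2 records -> empty list."""
    out: list[PairClassification] = []
    for i in range(len(records) - 1):
        r1, r2 = records[i], records[i + 1]
        du = r2.u_plus - r1.u_plus
        dx = r2.x_minus - r1.x_minus
        if r1.rr == 0.0:
            label, ppr = UNDEFINED, np.nan
        else:
            ppr = r2.rr / r1.rr
            if ppr < 1.0:
                label = PPD
            elif ppr == 1.0:
                label = tie_label
            elif du >= 0.0:
                label = PPF
            else:
                label = RECOVERY
        out.append(
            PairClassification(i, r1.spike_time, r2.spike_time, r1.rr, r2.rr,
                               ppr, du, dx, label)
        )
    return out


def mean_ppr(records: Sequence[ReleaseRecord]) -> float:
    """Averaged paired-pulse ratio <RR2>/<RR1> for a paired-pulse protocol.

    Records must alternate first/second pulses of each pair (the layout
    produced by a paired-pulse stimulus).
    """
    if len(records) < 2 or len(records) % 2:
        raise ValueError("need an even number (>= 2) of paired-pulse records")
    rr = np.array([r.rr for r in records])
    first, second = rr[0::2], rr[1::2]
    m1 = first.mean()
    if m1 == 0.0:
        raise ValueError("mean first-pulse release is zero; PPR undefined")
    return float(second.mean() / m1)


def _count(cls: Sequence[PairClassification], include_recovery_as_ppf: bool
           ) -> tuple[int, int, int, int]:
    labels = [c.label for c in cls]
    ppf = labels.count(PPF)
    ppd = labels.count(PPD)
    rec = labels.count(RECOVERY)
    und = labels.count(UNDEFINED)
    if include_recovery_as_ppf:
        ppf, rec = ppf + rec, 0
    return ppf, ppd, rec, und


def _summarize(per_trial: list[tuple[int, int, int, int]]) -> TrialSummary:
    n = len(per_trial)
    ppf = np.array([p[0] for p in per_trial], dtype=float)
    ppd = np.array([p[1] for p in per_trial], dtype=float)
    rec = np.array([p[2] for p in per_trial], dtype=float)
    und = int(sum(p[3] for p in per_trial))
    valid = ppd > 0
    ratios = ppf[valid] / ppd[valid]
    sd = (lambda v: float(np.std(v, ddof=1)) if n > 1 else None)
    total_ppd = ppd.sum()
    return TrialSummary(
        n_trials=n,
        mean_ppf=float(ppf.mean()), sd_ppf=sd(ppf),
        mean_ppd=float(ppd.mean()), sd_ppd=sd(ppd),
        mean_recovery=float(rec.mean()), sd_recovery=sd(rec),
        ratio_ppf_ppd=float(ratios.mean()) if ratios.size else np.nan,
        sd_ratio=float(np.std(ratios, ddof=1)) if ratios.size > 1 else None,
        n_ratio_trials=int(valid.sum()),
        pooled_ratio=float(ppf.sum() / total_ppd) if total_ppd else np.nan,
        n_undefined=und,
    )


def run_trial_ensemble(
    n_trials: int,
    rate: float,
    duration: float,
    syn: SynapseParams,
    astro: AstroParams | None = None,
    gres: GRESchedule | None = None,
    base_seed: int = 0,
    *,
    include_recovery_as_ppf: bool = False,
) -> tuple[TrialSummary, pd.DataFrame]:
    """Ensemble of independent Poisson trials, classified and aggregated.

    Trial k uses seed ``base_seed + k``.  Without an astrocyte (or with an
    empty GRE schedule) the control TM response is simulated.  Returns the
    summary plus a raster table (trial, spike_time_s, label) where the label
    marks the pair *ending* at that spike.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    gres = gres if gres is not None else GRESchedule(np.empty(0))
    per_trial: list[tuple[int, int, int, int]] = []
    raster_rows: list[tuple[int, float, str]] = []
    for k in range(n_trials):
        train = gen_poisson_train(rate, duration, base_seed + k)
        if astro is None or len(gres) == 0:
            records = simulate_train(train, syn)
        else:
            records, _ = simulate_coupled(train, gres, syn, astro)
        cls = classify_pairs(records)
        per_trial.append(_count(cls, include_recovery_as_ppf))
        raster_rows.extend((k, c.t2, c.label) for c in cls)
    raster = pd.DataFrame(raster_rows, columns=["trial", "spike_time_s", "label"])
    return _summarize(per_trial), raster


def sweep_gre_frequency(
    fc_values,
    n_trials: int,
    rate: float,
    duration: float,
    syn: SynapseParams,
    astro: AstroParams,
    base_seed: int = 0,
    *,
    include_recovery_as_ppf: bool = False,
) -> pd.DataFrame:
    """Ensemble statistics per GRE frequency (f_C = 0 rows are the control).

    The same trial seeds are reused across frequencies so that columns differ
    only through the gliotransmission schedule.
    """
    from .stimulus import gen_gre_schedule

    rows = []
    for fc in np.asarray(fc_values, dtype=float):
        if fc < 0:
            raise ValueError("GRE frequencies must be non-negative")
        gres = gen_gre_schedule(fc, duration)
        summary, _ = run_trial_ensemble(
            n_trials, rate, duration, syn,
            astro if fc > 0 else None, gres, base_seed,
            include_recovery_as_ppf=include_recovery_as_ppf,
        )
        rows.append({"f_c_hz": fc, **summary.to_dict()})
    return pd.DataFrame(rows)
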