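"""End-to-end orchestration: simulate -> analyze -> report.

Two study drivers mirror the two halves of the analysis: the breathing study
(trinarization -> cycles -> ICI -> Cliff's Delta -> clustering -> binomial
significance) and the electrophysiology study (drug effects, charge
densities, E/I ratio, bursts, paired synchrony, DF_GABA, LTD).  Every run is
deterministic under its seed and writes a manifest of all parameters actually
used next to its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import biophys, breath, events, groupdisc, synthdata
from .trace import DataError, Trace

__all__ = ["RunConfig", "run_breath_study", "run_ephys_study"]

log = logging.getLogger("rettphys")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run.

    Defaults equal the analysis constants of the study design: trinarization
    thresholds +0.15 / -0.4, a 25-frame smoothing window, detection threshold
    3x the noise SD, bursts of >= 3 events on a >= 60 pA elevation, k = 3
    clusters with 1/3 success probability, and LTD windows 20-25 / 50-55 min
    after washout.
    """

    seed: int = 0
    # breathing analysis
    upper: float = 0.15
    lower: float = -0.4
    window: int = 25
    k: int = 3
    linkage: str = "average"
    success_prob: float = 1.0 / 3.0
    breath_params: synthdata.BreathSimParams = field(
        default_factory=synthdata.BreathSimParams)
    # electrophysiology analysis
    threshold_mult: float = 3.0
    min_burst_events: int = 3
    burst_elevation_pA: float = 60.0
    washout_tol: float = 0.20
    psc_duration: float = 60.0
    spike_duration: float = 180.0
    drug_window: tuple[float, float] = (60.0, 90.0)
    iv_params: synthdata.IVSimParams = field(default_factory=synthdata.IVSimParams)
    ltd_noise_sd: float = 0.05

    def manifest(self) -> dict[str, Any]:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (tuple, list)):
                return [enc(x) for x in o]
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            return o
        return {f.name: enc(getattr(self, f.name)) for f in dataclasses.fields(self)}


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_breath_study(config: RunConfig, outdir: str | Path | None = None,
                     records: list[synthdata.BreathRecord] | None = None
                     ) -> dict[str, Any]:
    """Breathing study: per-animal ICI extraction, pairwise Cliff's Delta,
    hierarchical clustering and per-group binomial significance.

    ``records`` may supply pre-loaded traces; otherwise a cohort is simulated
    from ``config.breath_params`` (with the config seed).  Returns the report
    dict; when ``outdir`` is given also writes ICI/delta/label CSVs, a
    significance JSON and the parameter manifest.
    """
    if records is None:
        params = dataclasses.replace(config.breath_params, seed=config.seed)
        records = synthdata.gen_breath_cohort(params, window=config.window)
    if not records:
        raise DataError("empty cohort")
    samples = [breath.breath_pipeline(r.trace, config.upper, config.lower,
                                      config.window) for r in records]
    m = groupdisc.delta_matrix(samples)
    result = groupdisc.cluster_animals(m, k=config.k, linkage=config.linkage)
    sig = groupdisc.cluster_significance(result, [r.group for r in records],
                                         success_prob=config.success_prob)
    n_eff, eff_labels = groupdisc.effective_clusters(result)
    report = {
        "n_animals": len(records),
        "n_clusters_requested": config.k,
        "n_clusters_populated": int(np.unique(result.labels).size),
        "n_clusters_effective": n_eff,
        "labels": {aid: int(lb) for aid, lb in zip(result.animal_ids, result.labels)},
        "effective_labels": {aid: int(lb) for aid, lb
                             in zip(result.animal_ids, eff_labels)},
        "per_group": [dataclasses.asdict(s) for s in sig],
        "significant_groups": [s.group for s in sig if s.p_value < 0.01],
    }
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame([(s.animal_id, s.group, iv) for s in samples
                      for iv in s.intervals],
                     columns=["animal_id", "group", "interval_s"]
                     ).to_csv(out / "ici.csv", index=False)
        pd.DataFrame(m.delta, index=m.animal_ids, columns=m.animal_ids
                     ).to_csv(out / "delta_matrix.csv")
        pd.DataFrame({"animal_id": result.animal_ids, "cluster": result.labels,
                      "group": [r.group for r in records]}
                     ).to_csv(out / "clusters.csv", index=False)
        _write_json(report, out / "significance.json")
        _write_json(config.manifest(), out / "manifest.json")
        log.info("breath study written to %s", out)
    return report


def _ephys_cohort_metrics(params: synthdata.EphysSimParams, config: RunConfig,
                          seed: int) -> dict[str, Any]:
    """Analyze one simulated condition (one parameter set)."""
    p = dataclasses.replace(params, seed=seed)
    # drug response on a spike trace
    spike_tr, _ = synthdata.gen_spike_trace(p, duration=config.spike_duration,
                                            drug_window=config.drug_window)
    sd = p.noise_sd if p.noise_sd > 0 else 1.0
    spikes = events.detect_events(spike_tr, sd, polarity=p.polarity,
                                  threshold_mult=config.threshold_mult,
                                  refractory=0.002)
    t_drug0, t_drug1 = config.drug_window
    effect = events.drug_effect(
        spikes, (0.0, t_drug0), (t_drug0, t_drug1),
        (t_drug1 + 30.0, config.spike_duration), washout_tol=config.washout_tol)
    # PSC pair: charge density, bursts, synchrony
    tr_a, tr_b, _, _ = synthdata.gen_psc_pair(p, duration=config.psc_duration)
    train = events.detect_events(tr_a, sd, polarity=p.polarity,
                                 threshold_mult=config.threshold_mult,
                                 detrend=0.2)
    bursts = events.detect_bursts(train, tr_a, config.min_burst_events,
                                  config.burst_elevation_pA)
    cd = events.charge_density(train, tr_a.duration)
    r, _, _ = events.paired_correlation(tr_a, tr_b)
    return {
        "drug_effect": effect.normalized_effect,
        "washout_ok": effect.washout_ok,
        "charge_density_pC_per_s": cd,
        "n_bursts": len(bursts),
        "pearson_r": r,
    }


def run_ephys_study(config: RunConfig, outdir: str | Path | None = None,
                    conditions: dict[str, synthdata.EphysSimParams] | None = None
                    ) -> dict[str, Any]:
    """Electrophysiology study on simulated wt-like and Mecp2-like conditions.

    Default conditions encode the study's qualitative physiology: the wt-like
    condition has an inhibitory drug response (rate multiplier < 1) and no
    population bursts; the Mecp2-like condition has an excitatory response,
    bursts and pair-correlated activity.  The report also carries DF_GABA
    fits per condition and an LTD summary.  Returns an empty report with a
    warning for an empty condition set.
    """
    if conditions is None:
        conditions = {
            "wt": synthdata.EphysSimParams(drug_multiplier=0.5),
            "mecp2": synthdata.EphysSimParams(
                baseline_rate=3.0, drug_multiplier=2.0, pair_correlation=0.6,
                burst_spec=synthdata.BurstSpec()),
        }
    report: dict[str, Any] = {"conditions": {}}
    if not conditions:
        log.warning("empty cohort: nothing to analyze")
        report["warning"] = "empty cohort"
    for name, params in conditions.items():
        report["conditions"][name] = _ephys_cohort_metrics(params, config,
                                                           seed=config.seed)
    # DF_GABA from simulated single-channel I/V
    iv_params = dataclasses.replace(config.iv_params, seed=config.seed)
    fit = biophys.fit_iv(synthdata.gen_iv_dataset(iv_params))
    report["df_gaba_mV"] = fit.df_gaba_mV
    report["iv_slope_conductance_pS"] = fit.slope_conductance_pS
    # LTD
    series = synthdata.gen_ltd_series(noise_sd=config.ltd_noise_sd,
                                      seed=config.seed)
    summ = biophys.ltd_summary(series)
    report["ltd"] = {"early_pct": summ.early_pct, "early_sem": summ.early_sem,
                     "late_pct": summ.late_pct, "late_sem": summ.late_sem}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _write_json(report, out / "ephys_report.json")
        _write_json(config.manifest(), out / "manifest.json")
        log.info("ephys study written to %s", out)
    return report
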