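"""End-to-end synthetic cohort study driver.

Simulates a patient-like and a control-like group through the full pipeline
(voice F0 -> vocal response; EEG -> ERP peaks; theta SL -> degree-indexed
network metrics) with configurable group-effect injections, then runs the
group statistics: a two-way mixed ANOVA on vocal magnitudes, per-K Welch
tests on network metrics, and the behavioral/clinical correlations
(baseline variability vs. response magnitude; disease duration vs. P2).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import erp as erp_mod
from . import graph as graph_mod
from . import sl as sl_mod
from . import vocal as vocal_mod
from .config import DegreeSweep, EEGGroundTruth, ParadigmConfig, VocalGroundTruth
from .montage import MASTOIDS, STATS_ELECTRODES, default_montage
from .stats import mixed_anova_2way, pearson_correlation, per_k_group_comparison, ttest_two_sample
from .synth import generate_session

__all__ = ["CohortConfig", "CohortReport", "cohort_study"]

GROUPS = ("patient", "control")


@dataclass
class CohortConfig:
    """Cohort composition and injected group effects.

    Defaults mirror the study's group structure: 28 subjects per group, vocal
    response magnitudes near the reported group means (16.3 vs 12.2 cents),
    a P2 deficit in the patient-like group that deepens with disease
    duration, and stronger within-block theta coupling for patients.
    """

    n_per_group: int = 28
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)

    # vocal behaviour
    vocal_magnitude_cents: dict[str, float] = field(
        default_factory=lambda: {"patient": 16.3, "control": 12.2})
    vocal_magnitude_between_sd: float = 4.0
    vocal_latency_ms: float = 130.0
    vocal_latency_between_sd: float = 15.0
    jitter_sd_mean_cents: float = 5.0
    jitter_sd_between_sd: float = 1.5
    #: cents of extra response magnitude per cent of baseline jitter SD
    #: (induces the positive variability-magnitude correlation)
    jitter_magnitude_slope: float = 0.8

    # ERP
    n1_between_sd_uv: float = 0.6
    p2_between_sd_uv: float = 0.8
    p2_patient_deficit_uv: float = 1.0
    p2_duration_slope_uv_per_year: float = 0.08
    duration_range_years: tuple[float, float] = (2.0, 20.0)

    # theta coupling
    coupling: dict[str, float] = field(
        default_factory=lambda: {"patient": 0.65, "control": 0.35})
    coupling_between_sd: float = 0.08
    n_theta_blocks: int = 4
    theta_amp_uv: float = 10.0
    noise_sd_uv: float = 5.0

    # network analysis
    sweep: DegreeSweep = field(default_factory=DegreeSweep)
    n_surrogates: int = 30
    swaps_per_edge: int = 10
    sl_max_refs: int | None = 64
    sl_decimate_to_hz: float = 250.0

    electrodes: tuple[str, ...] = STATS_ELECTRODES

    @classmethod
    def small(cls) -> "CohortConfig":
        """Desk-scale preset with deliberately strong injected effects.

        Used to verify end-to-end effect propagation at small n; the injected
        separations are much larger than the study's clinical effect sizes so
        that effect *directions* are identifiable with few subjects.
        """
        paradigm = ParadigmConfig(n_vocalizations=6, eeg_channels=32)
        return cls(
            n_per_group=5,
            paradigm=paradigm,
            vocal_magnitude_cents={"patient": 18.0, "control": 10.0},
            vocal_magnitude_between_sd=2.5,
            p2_patient_deficit_uv=2.5,
            p2_between_sd_uv=0.6,
            coupling={"patient": 0.7, "control": 0.3},
            coupling_between_sd=0.05,
            sweep=DegreeSweep(9.0, 14.0, 1.0),
            n_surrogates=5,
            swaps_per_edge=5,
        )

    def null(self) -> "CohortConfig":
        """Copy with all group effects removed (for type-I style checks)."""
        mean_vocal = float(np.mean(list(self.vocal_magnitude_cents.values())))
        mean_coupling = float(np.mean(list(self.coupling.values())))
        return replace(
            self,
            vocal_magnitude_cents={g: mean_vocal for g in GROUPS},
            coupling={g: mean_coupling for g in GROUPS},
            p2_patient_deficit_uv=0.0,
            p2_duration_slope_uv_per_year=0.0,
        )


@dataclass
class CohortReport:
    subjects: pd.DataFrame
    vocal: pd.DataFrame
    erp: pd.DataFrame
    network: pd.DataFrame
    anova_vocal: dict
    per_k: pd.DataFrame
    correlations: dict
    directions: dict[str, bool]
    effect_flags: dict[str, bool]
    n_invalid_vocal: int
    seed: int | None = None


def _theta_blocks(cfg: CohortConfig) -> tuple[tuple[tuple[int, ...], float], ...]:
    labels = default_montage(cfg.paradigm.eeg_channels)
    scalp = [i for i, lab in enumerate(labels) if lab not in MASTOIDS]
    blocks = np.array_split(np.asarray(scalp), cfg.n_theta_blocks)
    return tuple(tuple(b.tolist()) for b in blocks)


def _condition_subset(eps: erp_mod.EpochSet, condition: float) -> erp_mod.EpochSet:
    sel = eps.magnitudes_cents == condition
    return erp_mod.EpochSet(
        data=eps.data[sel], times_ms=eps.times_ms, fs=eps.fs,
        channel_names=eps.channel_names,
        magnitudes_cents=eps.magnitudes_cents[sel],
        flags=None if eps.flags is None else eps.flags[sel],
        epoch_keep=None if eps.epoch_keep is None else eps.epoch_keep[sel],
        bad_channels=eps.bad_channels, file_ok=eps.file_ok)


def _simulate_subject(cfg: CohortConfig, group: str, rng: np.random.Generator):
    """Draw subject-level truths and generate one full session."""
    jitter = max(0.5, rng.normal(cfg.jitter_sd_mean_cents, cfg.jitter_sd_between_sd))
    magnitude = max(1.0, cfg.vocal_magnitude_cents[group]
                    + cfg.jitter_magnitude_slope * (jitter - cfg.jitter_sd_mean_cents)
                    + rng.normal(0.0, cfg.vocal_magnitude_between_sd))
    latency = float(np.clip(rng.normal(cfg.vocal_latency_ms, cfg.vocal_latency_between_sd),
                            70.0, 200.0))
    vt = VocalGroundTruth(response_magnitude_cents=magnitude,
                          response_latency_ms=latency,
                          jitter_sd_cents=jitter)

    duration = (rng.uniform(*cfg.duration_range_years) if group == "patient" else 0.0)
    n1_off = rng.normal(0.0, cfg.n1_between_sd_uv)
    p2_off = rng.normal(0.0, cfg.p2_between_sd_uv)
    deficit = (cfg.p2_patient_deficit_uv + cfg.p2_duration_slope_uv_per_year * duration
               if group == "patient" else 0.0)
    base = EEGGroundTruth()
    n1 = {m: (min(-0.5, a + n1_off), lat) for m, (a, lat) in base.n1.items()}
    p2 = {m: (max(0.5, a + p2_off - deficit), lat) for m, (a, lat) in base.p2.items()}
    strength = float(np.clip(rng.normal(cfg.coupling[group], cfg.coupling_between_sd),
                             0.02, 0.98))
    et = EEGGroundTruth(n1=n1, p2=p2,
                        theta_blocks=tuple((b, strength) for b in _theta_blocks(cfg)),
                        theta_amp_uv=cfg.theta_amp_uv,
                        noise_sd_uv=cfg.noise_sd_uv)
    session = generate_session(cfg.paradigm, vt, et, rng)
    truths = {"jitter_sd_true": jitter, "magnitude_true": magnitude,
              "latency_true": latency, "duration_years": duration,
              "coupling_true": strength,
              "p2_true_mean": float(np.mean([v[0] for v in p2.values()]))}
    return session, truths


def cohort_study(cfg: CohortConfig | None = None, seed: int | None = None) -> CohortReport:
    """Run the full two-group pipeline and group statistics."""
    cfg = cfg or CohortConfig()
    root = np.random.SeedSequence(seed)
    subj_rows, vocal_rows, erp_rows, net_rows = [], [], [], []

    for group in GROUPS:
        children = root.spawn(cfg.n_per_group)
        for s, child in enumerate(children):
            rng = np.random.default_rng(child)
            subject = f"{group[:1].upper()}{s + 1:02d}"
            session, truths = _simulate_subject(cfg, group, rng)
            subj_rows.append({"subject": subject, "group": group, **truths})

            # ---- vocal pipeline ----
            cents = vocal_mod.hz_to_cents(session.f0_hz)
            veps = vocal_mod.epoch_vocal(cents, cfg.paradigm.f0_sample_rate,
                                         session.event_onsets_s,
                                         session.event_magnitudes_cents)
            averages = vocal_mod.average_epochs(veps)
            sd_trials = vocal_mod.baseline_variability(veps, mode="trials")
            for cond, avg in averages.items():
                resp = vocal_mod.detect_vocal_response(avg, veps.times_ms)
                vocal_rows.append({
                    "subject": subject, "group": group, "condition": cond,
                    "valid": resp.valid, "magnitude_cents": resp.magnitude_cents,
                    "latency_ms": resp.latency_ms,
                    "baseline_sd_cents": sd_trials,
                    "baseline_sd_avg_cents": resp.baseline_sd_cents,
                })

            # ---- ERP pipeline ----
            eps, erp_avgs = erp_mod.erp_pipeline(
                session.eeg, cfg.paradigm.eeg_sample_rate,
                session.event_samples_eeg, session.event_magnitudes_cents,
                session.channel_names)
            for cond, avg in erp_avgs.items():
                for comp in ("N1", "P2"):
                    for elec in cfg.electrodes:
                        if elec not in avg.channel_names:
                            continue
                        pk = erp_mod.measure_peak(avg, comp, elec)
                        erp_rows.append({
                            "subject": subject, "group": group, "condition": cond,
                            "electrode": elec, "component": comp,
                            "amplitude_uv": pk.amplitude_uv,
                            "latency_ms": pk.latency_ms,
                        })

            # ---- theta connectivity and graph metrics ----
            theta = sl_mod.theta_filter(session.eeg, cfg.paradigm.eeg_sample_rate)
            teps = erp_mod.segment(theta, cfg.paradigm.eeg_sample_rate,
                                   session.event_samples_eeg,
                                   session.event_magnitudes_cents,
                                   session.channel_names)
            teps.epoch_keep = eps.epoch_keep
            teps.bad_channels = eps.bad_channels
            teps = sl_mod.decimate_epochs(teps, cfg.sl_decimate_to_hz)
            for cond in sorted(set(session.event_magnitudes_cents.tolist())):
                sub = _condition_subset(teps, cond)
                slm = sl_mod.sl_matrix(sub, max_refs=cfg.sl_max_refs,
                                       exclude=MASTOIDS)
                good = [i for i, name in enumerate(slm.channel_names)
                        if np.isfinite(slm.values[i]).any() and name not in MASTOIDS
                        and name not in sub.bad_channels]
                w = slm.values[np.ix_(good, good)]
                table = graph_mod.sweep_degrees(
                    w, cfg.sweep, n_surrogates=cfg.n_surrogates, seed=rng,
                    swaps_per_edge=cfg.swaps_per_edge)
                table.insert(0, "condition", cond)
                table.insert(0, "group", group)
                table.insert(0, "subject", subject)
                net_rows.append(table)

    subjects = pd.DataFrame(subj_rows)
    vocal = pd.DataFrame(vocal_rows)
    erp = pd.DataFrame(erp_rows)
    network = pd.concat(net_rows, ignore_index=True)

    return _report(cfg, seed, subjects, vocal, erp, network)


def _report(cfg, seed, subjects, vocal, erp, network) -> CohortReport:
    # subjects with an invalid response in any condition are excluded from
    # the vocal statistics (mirroring the study's exclusion of one subject)
    invalid_subjects = vocal.loc[~vocal.valid, "subject"].unique().tolist()
    vocal_ok = vocal[~vocal.subject.isin(invalid_subjects)]
    anova = mixed_anova_2way(vocal_ok, dv="magnitude_cents", within="condition",
                             between="group", subject="subject")

    p2 = (erp[erp.component == "P2"]
          .groupby(["subject", "group"], as_index=False)["amplitude_uv"].mean())
    p2_test = ttest_two_sample(p2.loc[p2.group == "patient", "amplitude_uv"],
                               p2.loc[p2.group == "control", "amplitude_uv"])

    per_subj = (vocal_ok.groupby(["subject", "group"], as_index=False)
                [["magnitude_cents", "baseline_sd_cents"]].mean())
    correlations = {}
    try:
        correlations["baseline_sd_vs_magnitude"] = pearson_correlation(
            per_subj.baseline_sd_cents, per_subj.magnitude_cents)
    except ValueError:
        correlations["baseline_sd_vs_magnitude"] = None
    pat = p2.merge(subjects[["subject", "duration_years"]], on="subject")
    pat = pat[pat.group == "patient"]
    try:
        correlations["duration_vs_p2"] = pearson_correlation(
            pat.duration_years, pat.amplitude_uv)
    except ValueError:
        correlations["duration_vs_p2"] = None

    have_swi = network["gamma"].notna().any() if "gamma" in network else False
    value_cols = ("C", "L", "gamma", "lambda") if have_swi else ("C", "L")
    per_k_frames = []
    for cond in sorted(network.condition.unique().tolist()):
        sub = network[network.condition == cond]
        tab = per_k_group_comparison(sub, value_cols=value_cols)
        tab.insert(0, "condition", cond)
        per_k_frames.append(tab)
    per_k = pd.concat(per_k_frames, ignore_index=True)

    def group_mean(df, col):
        g = df.groupby("group")[col].mean()
        return g.get("patient", np.nan), g.get("control", np.nan)

    v_p, v_c = group_mean(vocal_ok, "magnitude_cents")
    c_p, c_c = group_mean(network, "C")
    l_p, l_c = group_mean(network, "L")
    p2_p, p2_c = group_mean(p2, "amplitude_uv")
    directions = {
        "vocal_larger_in_patients": bool(v_p > v_c),
        "p2_smaller_in_patients": bool(p2_p < p2_c),
        "clustering_higher_in_patients": bool(c_p > c_c),
        "path_length_higher_in_patients": bool(l_p > l_c),
    }

    c_subj = network.groupby(["subject", "group"], as_index=False)[["C", "L"]].mean()
    c_test = ttest_two_sample(c_subj.loc[c_subj.group == "patient", "C"],
                              c_subj.loc[c_subj.group == "control", "C"])
    l_test = ttest_two_sample(c_subj.loc[c_subj.group == "patient", "L"],
                              c_subj.loc[c_subj.group == "control", "L"])
    effect_flags = {
        "vocal": bool(anova["between"].pvalue < 0.05
                      and directions["vocal_larger_in_patients"]),
        "p2": bool(p2_test.pvalue < 0.05 and directions["p2_smaller_in_patients"]),
        "clustering": bool(c_test.pvalue < 0.05
                           and directions["clustering_higher_in_patients"]),
        "path_length": bool(l_test.pvalue < 0.05
                            and directions["path_length_higher_in_patients"]),
    }
    return CohortReport(subjects=subjects, vocal=vocal, erp=erp, network=network,
                        anova_vocal=anova, per_k=per_k, correlations=correlations,
                        directions=directions, effect_flags=effect_flags,
                        n_invalid_vocal=len(invalid_subjects), seed=seed)
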