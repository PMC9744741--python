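"""End-to-end study orchestration: simulate → preprocess → features → stats.

``run_study`` executes the whole analysis on a synthetic cohort and returns a
:class:`StudyReport` mirroring a resting-state results section: per-band
group tests in both conditions (FDR-corrected), cluster-level contrasts for
the significant bands, PC1 correlations with cluster power, the IAF group
test and PC1 correlation, brain/behaviour DFA exponents and their
correlation (with the eyes-open scalp-level correlation clusters), and the
two arousal controls (eyes-closed global alpha, alpha reactivity).

Every reported p-value carries its seed, permutation count and family.
Runs are deterministic for a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .montage import Montage, make_montage
from .synth import CohortSpec, make_cohort, synth_eeg, synth_gaze
from .preprocess import preprocess_chain
from .spectral import (welch_psd, relative_power, detect_iaf,
                       DEFAULT_BANDS, DEFAULT_NORM_RANGE)
from .dynamics import (DFAParams, envelope_dfa_exponents, extract_fixations,
                       behavioural_dfa, ALPHA_BAND)
from . import stats as gstats

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "StudyReport", "run_study", "check_directions",
           "DIRECTION_TABLE"]


@dataclass(frozen=True)
class StudyConfig:
    """Fully serializable description of one study run."""
    cohort: CohortSpec = field(default_factory=CohortSpec)
    n_channels: int = 64
    target_fs: float = 250.0
    welch_resolution: float = 0.5
    norm_range: tuple = DEFAULT_NORM_RANGE
    iaf_range: tuple = (7.0, 13.0)
    envelope_order: int = 66
    dfa: DFAParams = field(default_factory=DFAParams)
    velocity_threshold: float = 30.0
    min_fix_ms: float = 50.0
    min_sacc_ms: float = 10.0
    n_perm: int = 1000
    cluster_alpha: float = 0.01
    alpha: float = 0.05
    fdr_q: float = 0.05
    reactivity_orientation: str = "eo_over_ec"
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cohort"]["group_params"] = {
            g: asdict(p) for g, p in self.cohort.group_params.items()}
        return d


@dataclass
class StudyReport:
    """Machine-readable study results; see module docstring for structure."""
    config: dict
    cohort_table: list
    band_tests: dict            # condition -> band -> {F, p_perm, p_fdr, significant}
    cluster_tests: dict         # condition -> band -> cluster summary
    pc1_cluster_correlations: dict   # condition -> band -> CorrelationResult dict
    iaf: dict
    dfa_summary: dict
    controls: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


CONDITIONS = ("eyes_open", "eyes_closed")

#: sign each headline association must show (against PC1 unless stated)
DIRECTION_TABLE = {
    "alpha_power_vs_pc1": +1,        # eyes-open alpha cluster power
    "beta_power_vs_pc1": -1,
    "gamma_power_vs_pc1": -1,
    "iaf_vs_pc1": -1,
    "brain_vs_behaviour_dfa": +1,    # eyes-open envelope vs fixation exponents
}


def _cluster_to_dict(res: gstats.ClusterResult, montage: Montage) -> dict:
    region_of = dict(zip(montage.labels, montage.regions))
    return {
        "clusters": [{
            "channels": list(ch),
            "size": s,
            "sign": sg,
            "p": p,
            "majority_region": _majority([region_of[c] for c in ch]),
        } for ch, s, sg, p in zip(res.clusters, res.cluster_sizes, res.signs,
                                  res.cluster_p)],
        "cluster_alpha": res.cluster_alpha,
        "alpha": res.alpha,
        "significant": list(res.significant),
    }


def _majority(tags: list) -> str:
    vals, counts = np.unique(tags, return_counts=True)
    return str(vals[np.argmax(counts)])


def _corr_dict(c: gstats.CorrelationResult) -> dict:
    return {"r": c.r, "p": c.p, "ci95": list(c.ci95), "n": c.n}


def run_study(config: StudyConfig = StudyConfig()) -> StudyReport:
    """Run the full pipeline on a generated cohort; deterministic given seed."""
    seed = config.seed
    montage = make_montage(config.n_channels)
    spec = dataclasses.replace(config.cohort, seed=seed)
    cohort = make_cohort(spec)
    n_sub = len(cohort)
    if n_sub == 0:
        raise ValueError("empty cohort")
    groups = np.array([s.group for s in cohort])
    pc1 = np.array([s.pc1_score for s in cohort])

    band_names = [b.name for b in DEFAULT_BANDS]
    n_ch = montage.n_channels
    rel = {c: np.full((n_sub, n_ch, len(band_names)), np.nan) for c in CONDITIONS}
    env_exp = {c: np.full((n_sub, n_ch), np.nan) for c in CONDITIONS}
    iaf_vals = np.full(n_sub, np.nan)
    iaf_ok = np.zeros(n_sub, dtype=bool)
    beh_exp = np.full(n_sub, np.nan)
    excluded = []

    for si, subj in enumerate(cohort):
        try:
            maps = {}
            for cond in CONDITIONS:
                rec = synth_eeg(subj, montage, cond, duration_s=spec.duration_s,
                                fs=spec.fs_eeg, seed=seed)
                rec, _rep = preprocess_chain(rec, montage,
                                             target_fs=config.target_fs)
                spectrum = welch_psd(rec, config.welch_resolution)
                bp = relative_power(spectrum, DEFAULT_BANDS, config.norm_range)
                rel[cond][si] = bp.values
                maps[cond] = bp
                env_exp[cond][si] = envelope_dfa_exponents(
                    rec, ALPHA_BAND, config.envelope_order, config.dfa)
                if cond == "eyes_closed":
                    res = detect_iaf(spectrum, montage, *config.iaf_range)
                    iaf_vals[si] = res.iaf
                    iaf_ok[si] = res.is_true_peak
            gaze = synth_gaze(subj, duration_s=spec.gaze_duration_s,
                              fs_gaze=spec.fs_gaze, seed=seed)
            fix = extract_fixations(gaze, config.velocity_threshold,
                                    config.min_fix_ms, config.min_sacc_ms)
            beh_exp[si] = behavioural_dfa(fix, config.dfa).exponent
        except ValueError as exc:  # incomplete subject: exclude with reason
            logger.warning("excluding %s: %s", subj.subject_id, exc)
            excluded.append({"subject_id": subj.subject_id, "reason": str(exc)})

    meta = {"seed": seed, "n_perm": config.n_perm}

    # --- band-level group tests (global = channel-mean relative power) -----
    scalp = montage.scalp_mask
    band_tests = {}
    cluster_tests = {}
    pc1_corrs = {}
    for cond in CONDITIONS:
        pvals = []
        entries = {}
        for bi, band in enumerate(band_names):
            vals = np.nanmean(rel[cond][:, scalp, bi], axis=1)
            res = gstats.perm_anova_global(vals, groups, config.n_perm,
                                           seed=_stat_seed(seed, cond, band))
            entries[band] = {"F": res.statistic, "p_perm": res.p_perm, **meta,
                             "family": f"{cond} bands"}
            pvals.append(res.p_perm)
        p_adj, reject = gstats.fdr_bh(pvals, config.fdr_q)
        for band, pa, rej in zip(band_names, p_adj, reject):
            entries[band]["p_fdr"] = float(pa)
            entries[band]["significant"] = bool(rej)
        band_tests[cond] = entries

        # --- scalp-level contrasts (all bands; the global band test is
        # reported alongside rather than used as a gate, since a focal effect
        # can be invisible in the channel-mean) --------------------------------
        cluster_tests[cond] = {}
        pc1_corrs[cond] = {}
        for bi, band in enumerate(band_names):
            res = gstats.cluster_perm_ttest(
                rel[cond][:, :, bi], groups, montage,
                cluster_alpha=config.cluster_alpha, alpha=config.alpha,
                n_perm=config.n_perm, seed=_stat_seed(seed, cond, band, "cl"))
            cdict = _cluster_to_dict(res, montage)
            cdict.update(meta, family=f"{cond} scalp clusters")
            cluster_tests[cond][band] = cdict
            for ci in res.significant:
                idx = [montage.labels.index(ch) for ch in res.clusters[ci]]
                cmean = rel[cond][:, idx, bi].mean(axis=1)
                corr = gstats.spearman(pc1, cmean)
                regs = [montage.regions[i] for i in idx]
                pc1_corrs[cond].setdefault(band, []).append(
                    {**_corr_dict(corr), "cluster_sign": res.signs[ci],
                     "cluster_size": res.cluster_sizes[ci],
                     "region_counts": {r: regs.count(r) for r in set(regs)},
                     **meta})

    # --- IAF ----------------------------------------------------------------
    ok = iaf_ok & ~np.isnan(iaf_vals)
    iaf_report = {"values": iaf_vals.tolist(), "true_peak": iaf_ok.tolist(),
                  "n_excluded_no_peak": int((~ok).sum())}
    if ok.sum() >= 4 and len(np.unique(groups[ok])) == 2:
        res = gstats.perm_ttest(iaf_vals[ok], groups[ok], config.n_perm,
                                seed=_stat_seed(seed, "iaf"))
        iaf_report["group_test"] = {"t": res.statistic, "p_perm": res.p_perm,
                                    **meta, "family": "iaf"}
        iaf_report["pc1_correlation"] = _corr_dict(gstats.spearman(pc1[ok],
                                                                   iaf_vals[ok]))
        iaf_report["group_medians"] = {
            str(g): float(np.median(iaf_vals[ok & (groups == g)]))
            for g in np.unique(groups)}

    # --- DFA: brain vs behaviour --------------------------------------------
    brain_mean = {c: np.nanmean(env_exp[c][:, scalp], axis=1) for c in CONDITIONS}
    dfa_summary = {
        "behavioural_exponents": beh_exp.tolist(),
        "brain_mean_exponents": {c: brain_mean[c].tolist() for c in CONDITIONS},
        "brain_vs_behaviour": {
            c: {**_corr_dict(gstats.spearman(brain_mean[c], beh_exp)), **meta}
            for c in CONDITIONS},
    }
    res = gstats.cluster_perm_correlation(
        env_exp["eyes_open"], beh_exp, montage,
        cluster_alpha=config.cluster_alpha, alpha=config.alpha,
        n_perm=config.n_perm, seed=_stat_seed(seed, "dfa_cluster"))
    cdict = _cluster_to_dict(res, montage)
    cdict.update(meta, family="eyes_open dfa clusters")
    dfa_summary["eyes_open_scalp_correlation"] = cdict
    for ci in res.significant:
        idx = [montage.labels.index(ch) for ch in res.clusters[ci]]
        cmean = env_exp["eyes_open"][:, idx].mean(axis=1)
        dfa_summary.setdefault("cluster_correlations", []).append(
            {**_corr_dict(gstats.spearman(cmean, beh_exp)),
             "cluster_sign": res.signs[ci]})

    # --- controls -------------------------------------------------------------
    alpha_bi = band_names.index("alpha")
    ec_alpha = np.nanmean(rel["eyes_closed"][:, scalp, alpha_bi], axis=1)
    eo_alpha = np.nanmean(rel["eyes_open"][:, scalp, alpha_bi], axis=1)
    if config.reactivity_orientation == "eo_over_ec":
        react = eo_alpha / ec_alpha
    else:
        react = ec_alpha / eo_alpha
    res_ec = gstats.perm_ttest(ec_alpha, groups, config.n_perm,
                               seed=_stat_seed(seed, "ctrl_ec"))
    res_re = gstats.perm_ttest(react, groups, config.n_perm,
                               seed=_stat_seed(seed, "ctrl_react"))
    controls = {
        "eyes_closed_global_alpha": {"t": res_ec.statistic, "p_perm": res_ec.p_perm,
                                     "cohens_d": _cohens_d(ec_alpha, groups),
                                     "family": "controls", **meta},
        "alpha_reactivity": {"t": res_re.statistic, "p_perm": res_re.p_perm,
                             "orientation": config.reactivity_orientation,
                             "cohens_d": _cohens_d(react, groups),
                             "family": "controls", **meta},
    }

    cohort_table = [dataclasses.asdict(s) for s in cohort]
    for row in cohort_table:
        row["excluded"] = row["subject_id"] in {e["subject_id"] for e in excluded}

    return StudyReport(config=config.to_dict(), cohort_table=cohort_table,
                       band_tests=band_tests, cluster_tests=cluster_tests,
                       pc1_cluster_correlations=pc1_corrs, iaf=iaf_report,
                       dfa_summary=dfa_summary, controls=controls)


def _stat_seed(seed: int, *parts) -> np.random.Generator:
    import zlib
    key = tuple(zlib.crc32(str(p).encode()) for p in parts)
    return np.random.Generator(np.random.PCG64(
        np.random.SeedSequence(seed, spawn_key=(9,) + key)))


def _cohens_d(values: np.ndarray, groups: np.ndarray) -> float:
    labels = np.unique(groups)
    a, b = values[groups == labels[0]], values[groups == labels[1]]
    sp = np.sqrt((((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
                 / (len(a) + len(b) - 2))
    return float((a.mean() - b.mean()) / sp) if sp > 0 else 0.0


def check_directions(report: StudyReport) -> dict:
    """Evaluate the sign of each headline association against the expected table.

    Returns ``{effect: {"expected", "observed_r", "status"}}``.  A matching
    sign is a ``pass``; an opposite sign is a ``fail`` only when that
    correlation is itself nominally significant (p < 0.05) — an insignificant
    wrong-sign estimate, or a missing cluster (e.g. on a null cohort), is
    ``inconclusive`` rather than failed.
    """
    def status_of(r, p, expected):
        if r is None or np.isnan(r):
            return "inconclusive"
        if np.sign(r) == expected:
            return "pass"
        return "fail" if (p is not None and p < 0.05) else "inconclusive"

    out = {}
    pc = report.pc1_cluster_correlations.get("eyes_open", {})
    pc1 = np.array([row["pc1_score"] for row in report.cohort_table])
    home = {"alpha": "occipital", "beta": "frontal", "gamma": "occipital"}
    for band, key in (("alpha", "alpha_power_vs_pc1"),
                      ("beta", "beta_power_vs_pc1"),
                      ("gamma", "gamma_power_vs_pc1")):
        expected = DIRECTION_TABLE[key]
        entries = pc.get(band)
        if not entries:
            out[key] = {"expected": expected, "observed_r": None,
                        "status": "inconclusive"}
            continue
        # the claims are region-qualified (occipital alpha/gamma, frontal
        # beta): judge on the cluster covering most of the home region,
        # breaking ties by cluster size
        best = max(entries, key=lambda e: (
            e.get("region_counts", {}).get(home[band], 0), e["cluster_size"]))
        out[key] = {"expected": expected, "observed_r": best["r"],
                    "status": status_of(best["r"], best.get("p"), expected)}
    key = "iaf_vs_pc1"
    iaf_corr = report.iaf.get("pc1_correlation")
    if iaf_corr is None:
        out[key] = {"expected": DIRECTION_TABLE[key], "observed_r": None,
                    "status": "inconclusive"}
    else:
        out[key] = {"expected": DIRECTION_TABLE[key], "observed_r": iaf_corr["r"],
                    "status": status_of(iaf_corr["r"], iaf_corr.get("p"),
                                        DIRECTION_TABLE[key])}
    key = "brain_vs_behaviour_dfa"
    bb = report.dfa_summary["brain_vs_behaviour"]["eyes_open"]
    out[key] = {"expected": DIRECTION_TABLE[key], "observed_r": bb["r"],
                "status": status_of(bb["r"], bb.get("p"), DIRECTION_TABLE[key])}
    return out
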