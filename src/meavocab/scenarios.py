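"""Reference synthetic studies exercising the full pipeline.

Each scenario simulates a recording with the generator's standard
conditions, runs the complete analysis stack on it, and reports recovery
statistics against the planted ground truth.  Problem sizes (epoch lengths
of 1.5-2.1 h, ~700-1000 bursts per epoch) are chosen so each study runs in
a few minutes on one CPU while keeping Monte-Carlo noise well below the
effects being measured; docs/methods.md discusses the choices.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .bursts import Burst
from .evoked import define_sites, label_clusters, select_sites, site_summary
from .geometry import make_geometry
from .pipeline import (analyze_epoch, build_vocabulary, extract_evoked_responses,
                       match_clusters_to_templates, match_onsets)
from .plasticity import basin_analysis, evoked_variability, pattern_existence_change
from .synthetic import SimulationConfig, make_templates, simulate_evoked_session, simulate_recording

#: probe sites mapped to planted templates in the reference studies
ROBUST_SITE_MAP = {3: 0, 16: 1, 17: 2}


def _templates_for(seed: int, k: int, geometry, attempts: int = 5):
    """Draw the study's templates; redraw on the rare unplaceable geometry."""
    for i in range(attempts):
        try:
            return make_templates(k, geometry, seed=seed + 1_000_003 * i)
        except RuntimeError:
            continue
    raise RuntimeError(f"could not place {k} templates near seed {seed}")


def _truth_labels(bursts: list[Burst], ground_truth, tol_ms: float = 50.0) -> np.ndarray:
    onsets = ground_truth.onset_ms.to_numpy()
    labels = np.full(len(bursts), -9)
    for i, b in enumerate(bursts):
        j = int(np.argmin(np.abs(onsets - b.start_ms)))
        if abs(onsets[j] - b.start_ms) <= tol_ms:
            labels[i] = ground_truth.template.iloc[j]
    return labels


def run_spontaneous_recovery(seed: int, k_templates: int = 9,
                             epoch_hours: float = 2.1) -> dict:
    """Simulate one spontaneous epoch (~1000 bursts at 8/min) and recover
    the planted vocabulary: detection recall/precision against ground-truth
    onsets and adjusted Rand index of the clustering against template
    labels."""
    geometry = make_geometry()
    templates = _templates_for(seed, k_templates, geometry)
    config = SimulationConfig(templates=templates, seed=seed + 1,
                              epoch_duration_hours=epoch_hours)
    events, gt = simulate_recording(config, geometry, "before")
    ana = analyze_epoch(events, geometry, duration_ms=epoch_hours * 3.6e6)
    recall, precision, _ = match_onsets([b.start_ms for b in ana.bursts],
                                        gt.onset_ms.to_numpy())
    fit = build_vocabulary(ana.bursts, geometry, seed=seed)
    labels = _truth_labels(ana.bursts, gt)
    ari = adjusted_rand_score(labels, fit.vocabulary.labels)
    return {"geometry": geometry, "templates": templates, "config": config,
            "analysis": ana, "ground_truth": gt, "fit": fit,
            "truth_labels": labels, "n_bursts": len(ana.bursts),
            "recall": recall, "precision": precision, "ari": float(ari)}


def run_probe_analysis(recovery: dict) -> dict:
    """Probe all 20 stimulation sites (30 pulses each) on the recovered
    network: robust sites are mapped to planted templates, the rest evoke
    random high-noise responses.  Reports per-site robustness/existence,
    the selected sites, and the fraction of robust-site repetitions
    explained by the cluster that recovered the mapped template."""
    geometry = recovery["geometry"]
    vocab = recovery["fit"].vocabulary
    spontaneous = recovery["analysis"].bursts
    site_map = {sid: None for sid in range(1, 21)}
    site_map.update(ROBUST_SITE_MAP)
    events, gt, log = simulate_evoked_session(recovery["config"], geometry,
                                              site_map=site_map,
                                              inject_artifacts=True)
    by_site, _ = extract_evoked_responses(events, log, geometry)
    sites = {s.site_id: s for s in define_sites(geometry)}
    summaries = []
    for sid, responses in sorted(by_site.items()):
        others = [b for s2, bs in by_site.items() if s2 != sid for b in bs[:5]]
        summaries.append(site_summary(sites[sid], responses, spontaneous, vocab,
                                      across_responses=others))
    selection = select_sites(summaries)
    stim_clusters, nonstim_clusters = label_clusters(
        [s for s in summaries if s.site_id in selection.selected], vocab)

    cluster_of = {t: c for c, t in
                  match_clusters_to_templates(vocab, recovery["truth_labels"]).items()}
    matched = total = 0
    for sid, tid in ROBUST_SITE_MAP.items():
        s = next(x for x in summaries if x.site_id == sid)
        matched += sum(1 for c in s.explaining if c == cluster_of.get(tid))
        total += len(s.explaining)
    return {"summaries": summaries, "selection": selection,
            "stimulated_clusters": stim_clusters,
            "non_stimulated_clusters": nonstim_clusters,
            "matched_fraction": matched / total if total else np.nan,
            "robust_robustness": [s.robustness for s in summaries
                                  if s.site_id in ROBUST_SITE_MAP]}


def run_plasticity_experiment(seed: int, k_templates: int = 9,
                              epoch_hours: float = 2.0,
                              n_ref: int = 8) -> dict:
    """Full before/after study with three stimulated (prominent) patterns.

    Stimulated templates hold 20% of the spontaneous weight each before
    stimulation (robust stimulation sites evoke prominent vocabulary
    patterns); after stimulation they drop to the residual weight and
    their basins emit disrupted, non-converging bursts.  Reports per-cluster
    dCDF between epochs, the basin analysis for one stimulated and one
    non-stimulated cluster, and the evoked-variability series of a
    stimulation session with its noise ramp."""
    geometry = make_geometry()
    templates = _templates_for(seed, k_templates, geometry)
    weights = np.array([0.20] * 3 + [0.40 / (k_templates - 3)] * (k_templates - 3))
    config = SimulationConfig(templates=templates, seed=seed + 1,
                              epoch_duration_hours=epoch_hours,
                              stimulated_templates=(0, 1, 2),
                              weights_before=weights)
    ev_b, gt_b = simulate_recording(config, geometry, "before")
    before = analyze_epoch(ev_b, geometry, duration_ms=epoch_hours * 3.6e6)
    ev_a, gt_a = simulate_recording(config, geometry, "after")
    after = analyze_epoch(ev_a, geometry, duration_ms=epoch_hours * 3.6e6,
                          epoch="after")
    fit = build_vocabulary(before.bursts, geometry, seed=seed)
    vocab = fit.vocabulary
    labels = _truth_labels(before.bursts, gt_b)
    cluster_to_template = match_clusters_to_templates(vocab, labels)
    stim_clusters = [c for c, t in cluster_to_template.items() if t in (0, 1, 2)]
    nonstim_clusters = [c for c in vocab.cluster_ids if c not in stim_clusters]

    stim_results, nonstim_results = [], []
    for c in vocab.cluster_ids:
        ref = [before.bursts[i] for i in vocab.members(c)][:n_ref]
        res = pattern_existence_change(ref, before.bursts, after.bursts,
                                       pattern=int(c))
        (stim_results if c in stim_clusters else nonstim_results).append(res)

    init_thr = fit.thresholds.initial_thresholds["corr2"]
    basin_stim = basin_analysis(before.bursts, after.bursts,
                                [before.bursts[i] for i in vocab.members(stim_clusters[0])],
                                init_thr, vocab=vocab,
                                reference_cluster=stim_clusters[0])
    basin_nonstim = basin_analysis(before.bursts, after.bursts,
                                   [before.bursts[i] for i in vocab.members(nonstim_clusters[0])],
                                   init_thr, vocab=vocab,
                                   reference_cluster=nonstim_clusters[0])

    # stimulation session: responses grow more stereotyped along the ramp
    sess_cfg = SimulationConfig(templates=templates, seed=seed + 2,
                                reps_per_site=60,
                                stimulated_templates=(0, 1, 2),
                                weights_before=weights)
    ev_s, _, log = simulate_evoked_session(sess_cfg, geometry,
                                           site_map=ROBUST_SITE_MAP, epoch="after")
    by_site, _ = extract_evoked_responses(ev_s, log, geometry)
    responses = by_site[min(by_site)]
    variability = evoked_variability(responses,
                                     np.array([b.start_ms for b in responses]),
                                     window_min=2.5)
    return {"fit": fit, "before": before, "after": after,
            "stim_results": stim_results, "nonstim_results": nonstim_results,
            "basin_stim": basin_stim, "basin_nonstim": basin_nonstim,
            "variability": variability,
            "stim_clusters": stim_clusters, "nonstim_clusters": nonstim_clusters}


def run_null_calibration(seed: int, n_seeds: int = 100) -> dict:
    """Repeat the control-group comparison (no planted effect) across seeds
    and report how often the one-sided test stays above p = 0.05."""
    from .calibration import null_calibration_pvalue
    base = np.random.SeedSequence(seed).generate_state(n_seeds) % (2 ** 31)
    pvals = np.array([null_calibration_pvalue(int(s)) for s in base])
    return {"p_values": pvals, "fraction_above_05": float((pvals > 0.05).mean())}
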