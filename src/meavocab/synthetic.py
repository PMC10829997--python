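"""Synthetic MEA recordings with a planted burst vocabulary.

Generates seeded spike-event tables emulating the phenomenology of cultured
cortical networks on a 120-electrode array: spontaneous network bursts at
~8/min lasting 100-250 ms, drawn from a finite set of spatiotemporal
templates with convergent (attractor-like) dynamics; evoked responses to
6-electrode stimulation sites; and before/after epochs in which stimulated
templates all but vanish from spontaneous activity while evoked responses
grow more stereotyped.  Every generated burst is recorded in a ground-truth
table, so detection, clustering, the explains procedure and the plasticity
statistics can all be checked against planted labels.

A template is a moving 2-D Gaussian activity bump: a smooth random path
over the array times a single-peaked amplitude envelope.  A realization
perturbs the path start and the per-electrode gains with noise that decays
exponentially (the convergence half-life), so early bins vary between
repetitions while late bins converge to the template — the attractor
signature.  Spikes are emitted per electrode by thinning an inhomogeneous
Poisson intensity; no biophysics is claimed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .evoked import define_sites
from .geometry import ElectrodeGeometry, make_geometry

TIME_DECIMALS = 1          # event times stored to 0.1 ms
DEFAULT_SEPARATION = 0.6   # max allowed noiseless corr2 between templates


@dataclass
class BurstTemplate:
    """One spatiotemporal burst pattern (a planted attractor).

    ``path(t)`` is sampled at 1 ms on [0, duration); ``envelope`` is the
    nonnegative amplitude factor (peak 1) rising to a single maximum then
    decaying.  ``footprint`` is the 120-d expected initial-state vector
    (expected spike count per electrode in the first 5 ms bin).
    """

    template_id: int
    duration_ms: float
    path_mm: np.ndarray = field(repr=False)       # (duration, 2)
    envelope: np.ndarray = field(repr=False)      # (duration,)
    footprint: np.ndarray = field(repr=False)     # (N,)
    convergence_half_life_ms: float = 30.0
    bump_sigma_mm: float = 2.5
    peak_rate_hz: float = 4000.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic network.

    Defaults are the conditions the analyses are designed around: bursts at
    8/min, 10 s inter-stimulus interval, 30 repetitions per probed site, a
    1 s refractory gap between burst onsets, and a post-stimulation epoch
    in which each stimulated template's spontaneous weight drops to a
    residual 0.02.  The probability mass removed from the stimulated
    templates is not redistributed over the surviving templates — those
    keep their original frequencies — but goes to *remapped* bursts:
    bursts still launched from a stimulated template's initial-state
    region whose flattened basin no longer pulls them in; they wander
    around the old pathway with amplified, non-decaying realization noise
    and never converge (``basin_remap_fraction`` overrides the remap
    probability explicitly).
    """

    templates: list[BurstTemplate]
    seed: int = 0
    weights_before: np.ndarray | None = None     # default uniform
    weights_after: np.ndarray | None = None      # default: residual rule
    stimulated_templates: tuple[int, ...] = ()
    burst_rate_per_min: float = 8.0
    baseline_hz: float = 0.2
    noise_scale: float = 1.0
    epoch_duration_hours: float = 1.0
    refractory_ms: float = 1000.0
    isi_s: float = 10.0
    reps_per_site: int = 30
    residual_weight: float = 0.02
    basin_remap_fraction: float | None = None   # default: the removed stim mass
    disruption_noise_factor: float = 6.0        # noise gain for remapped bursts
    disruption_half_life_ms: float = 8.0       # divergence time constant of remapped bursts
    latency_ms: float = 5.0
    path_jitter_mm: float = 0.6
    gain_noise_sd: float = 0.3
    amp_jitter_sd: float = 0.1

    def __post_init__(self):
        if self.burst_rate_per_min < 0 or self.baseline_hz < 0:
            raise ValueError("rates must be nonnegative")
        k = len(self.templates)
        if self.weights_before is None:
            self.weights_before = np.full(k, 1.0 / k) if k else np.empty(0)
        self.weights_before = np.asarray(self.weights_before, dtype=float)
        if k and abs(self.weights_before.sum() - 1.0) > 1e-9:
            raise ValueError("weights_before must sum to 1")
        if self.weights_after is None and k:
            w = self.weights_before.copy()
            for tid in self.stimulated_templates:
                w[tid] = min(w[tid], self.residual_weight)
            self._removed_mass = float(1.0 - w.sum())
            self.weights_after = w / w.sum()
        elif self.weights_after is not None:
            self.weights_after = np.asarray(self.weights_after, dtype=float)
            if abs(self.weights_after.sum() - 1.0) > 1e-9:
                raise ValueError("weights_after must sum to 1")
            self._removed_mass = 0.0
        else:
            self._removed_mass = 0.0

    def weights_for(self, epoch: str) -> np.ndarray:
        return self.weights_after if epoch == "after" else self.weights_before

    @property
    def remap_prob(self) -> float:
        """After-epoch probability that a burst is a remapped (disrupted) one."""
        if self.basin_remap_fraction is not None:
            return float(self.basin_remap_fraction)
        return self._removed_mass


_EPOCH_CODES = {"before": 1, "after": 2, "control": 3, "probe": 4, "stim": 5}


def _epoch_rng(seed: int, epoch: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _EPOCH_CODES.get(epoch, 9)]))


def _make_envelope(duration_ms: float, rise_ms: float = 15.0) -> np.ndarray:
    """Single-peaked amplitude envelope on a 1 ms grid, normalized to peak 1.

    Product of a saturating rise and an exponential decay.  Network bursts
    recruit abruptly, so the envelope starts at a substantial fraction of
    its peak; the burst's first bin then carries an informative initial
    state.
    """
    t = np.arange(duration_ms)
    decay = duration_ms / 3.0
    env = (1.0 - np.exp(-(t + 15.0) / rise_ms)) * np.exp(-t / decay)
    return env / env.max()


def _make_path(duration_ms: float, geometry: ElectrodeGeometry,
               rng: np.random.Generator, margin_mm: float = 1.0) -> np.ndarray:
    """Smooth random 2-D path within the array bounding box (1 ms grid)."""
    xmin, xmax, ymin, ymax = geometry.bounding_box
    knots_t = np.linspace(0, duration_ms, 4)
    kx = rng.uniform(xmin + margin_mm, xmax - margin_mm, 4)
    ky = rng.uniform(ymin + margin_mm, ymax - margin_mm, 4)
    t = np.arange(duration_ms)
    path = np.column_stack([CubicSpline(knots_t, kx)(t), CubicSpline(knots_t, ky)(t)])
    path[:, 0] = np.clip(path[:, 0], xmin, xmax)
    path[:, 1] = np.clip(path[:, 1], ymin, ymax)
    return path


#: ignition phase: the bump starts at this fraction of its full width and
#: widens with a 20 ms time constant — bursts nucleate locally, then recruit
IGNITION_FRAC = 0.5
IGNITION_TAU_MS = 20.0


def _bump_sigma_t(sigma_mm: float, n_t: int) -> np.ndarray:
    t = np.arange(n_t)
    return sigma_mm * (1.0 - IGNITION_FRAC * np.exp(-t / IGNITION_TAU_MS))


def _bump(geometry: ElectrodeGeometry, centers: np.ndarray,
          sigma_mm: float | np.ndarray) -> np.ndarray:
    """Gaussian bump activity, shape (N, T) for centers of shape (T, 2).

    ``sigma_mm`` may be a scalar or a per-time-bin array (ignition phase).
    """
    d2 = ((geometry.coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / (2.0 * np.asarray(sigma_mm) ** 2))


def template_intensity(template: BurstTemplate, geometry: ElectrodeGeometry
                       ) -> np.ndarray:
    """Noiseless intensity (Hz), shape (N, duration) on the 1 ms grid."""
    sig = _bump_sigma_t(template.bump_sigma_mm, len(template.envelope))
    bump = _bump(geometry, template.path_mm, sig)
    return template.peak_rate_hz * template.envelope[None, :] * bump


def realization_intensity(template: BurstTemplate, geometry: ElectrodeGeometry,
                          rng: np.random.Generator, noise_scale: float,
                          path_jitter_mm: float = 1.5,
                          gain_noise_sd: float = 0.5,
                          amp_jitter_sd: float = 0.1,
                          start_center_mm: np.ndarray | None = None,
                          blend_ms: float = 12.0,
                          noise_envelope: str = "decay") -> np.ndarray:
    """Noisy realization of a template's intensity (Hz), shape (N, duration).

    The path start is offset by a 2-D Gaussian jitter and the per-electrode
    gains by multiplicative noise; with the default ``noise_envelope=
    'decay'`` both decay with the template's convergence half-life, so
    realizations converge onto the template within the burst.
    ``noise_envelope='grow'`` inverts the time course — the realization
    starts exactly on the template and diverges from it (a disrupted,
    non-attracting pathway).  ``start_center_mm`` (evoked responses) pins
    the initial bump to a given point — e.g. a stimulation site's
    centroid — blending into the template path over ``blend_ms``.
    """
    d = len(template.envelope)
    t = np.arange(d)
    decay = np.exp(-np.log(2.0) * t / template.convergence_half_life_ms)
    if noise_envelope == "grow":
        decay = 1.0 - decay
    elif noise_envelope != "decay":
        raise ValueError("noise_envelope must be 'decay' or 'grow'")
    offset = rng.normal(0.0, path_jitter_mm * noise_scale, 2)
    centers = template.path_mm + offset * decay[:, None]
    if start_center_mm is not None:
        w = np.minimum(t / blend_ms, 1.0)[:, None]
        centers = (1.0 - w) * np.asarray(start_center_mm)[None, :] + w * centers
    bump = _bump(geometry, centers, _bump_sigma_t(template.bump_sigma_mm, d))
    gains = 1.0 + (gain_noise_sd * noise_scale) \
        * rng.normal(size=geometry.n_electrodes)[:, None] * decay[None, :]
    amp = template.peak_rate_hz * max(0.0, 1.0 + amp_jitter_sd * noise_scale * rng.normal())
    lam = amp * template.envelope[None, :] * bump * np.maximum(gains, 0.0)
    return np.maximum(lam, 0.0)


def render_burst_matrix(intensity_hz: np.ndarray, bin_ms: float = 5.0,
                        window_ms: float = 100.0) -> np.ndarray:
    """Integrate a 1 ms intensity into expected spike counts per bin.

    Returns the (N, window/bin) matrix of expected counts over the first
    ``window_ms`` of the burst — the noise-free analogue of the smoothed,
    binned activity the preprocessing stage produces.
    """
    n, d = intensity_hz.shape
    t_bins = int(round(window_ms / bin_ms))
    out = np.zeros((n, t_bins))
    for b in range(t_bins):
        lo, hi = int(b * bin_ms), int(min((b + 1) * bin_ms, d))
        if lo >= d:
            break
        out[:, b] = intensity_hz[:, lo:hi].sum(axis=1) / 1000.0
    return out


def noiseless_burst_matrix(template: BurstTemplate, geometry: ElectrodeGeometry,
                           bin_ms: float = 5.0, window_ms: float = 100.0
                           ) -> np.ndarray:
    return render_burst_matrix(template_intensity(template, geometry),
                               bin_ms, window_ms)


def _corr2_flat(a: np.ndarray, b: np.ndarray) -> float:
    a = a.ravel() - a.mean()
    b = b.ravel() - b.mean()
    return float(a @ b / np.sqrt((a @ a) * (b @ b)))


def make_templates(k: int, geometry: ElectrodeGeometry | None = None,
                   seed: int = 0,
                   duration_range_ms: tuple[float, float] = (100.0, 250.0),
                   convergence_half_life_ms: float = 30.0,
                   separation: float = DEFAULT_SEPARATION,
                   bump_sigma_mm: float = 2.5,
                   peak_rate_hz: float = 4000.0,
                   min_start_separation_mm: float = 2.5,
                   max_tries_per_template: int = 600) -> list[BurstTemplate]:
    """Draw ``k`` pairwise-distinguishable burst templates.

    Templates are rejection-sampled until the corr2 between any two
    noiseless realizations is below ``separation`` (default 0.6) and the
    path starts are at least ``min_start_separation_mm`` apart (distinct
    attractors occupy distinct initial-state regions).  Raises if a slot
    cannot be filled within ``max_tries_per_template`` proposals.
    Deterministic under ``seed``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    geometry = geometry or make_geometry()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    templates: list[BurstTemplate] = []
    mats: list[np.ndarray] = []
    for tid in range(k):
        for attempt in range(max_tries_per_template):
            duration = float(np.round(rng.uniform(*duration_range_ms)))
            path = _make_path(duration, geometry, rng)
            env = _make_envelope(duration)
            tmpl = BurstTemplate(template_id=tid, duration_ms=duration,
                                 path_mm=path, envelope=env,
                                 footprint=np.empty(0),
                                 convergence_half_life_ms=convergence_half_life_ms,
                                 bump_sigma_mm=bump_sigma_mm,
                                 peak_rate_hz=peak_rate_hz)
            if any(np.linalg.norm(path[0] - prev.path_mm[0]) < min_start_separation_mm
                   for prev in templates):
                continue
            m = noiseless_burst_matrix(tmpl, geometry)
            if all(_corr2_flat(m, prev) < separation for prev in mats):
                tmpl.footprint = m[:, 0].copy()
                templates.append(tmpl)
                mats.append(m)
                break
        else:
            raise RuntimeError(
                f"could not place template {tid} below corr2 {separation} "
                f"after {max_tries_per_template} proposals; reduce k or relax "
                "the separation bound")
    return templates


def _thin_spikes(intensity_hz: np.ndarray, rng: np.random.Generator,
                 t0_ms: float) -> tuple[np.ndarray, np.ndarray]:
    """Sample spikes from a per-electrode inhomogeneous Poisson intensity.

    Thinning: per electrode, candidates are drawn homogeneously at the
    electrode's peak rate and kept with probability lambda(t)/lambda_max,
    with lambda piecewise constant on the 1 ms grid — exact for that
    intensity.  Returns (electrode, time_ms) arrays, unsorted.
    """
    n, d = intensity_hz.shape
    lam_max = intensity_hz.max(axis=1)
    counts = rng.poisson(lam_max * d / 1000.0)
    tot = int(counts.sum())
    if tot == 0:
        return np.empty(0, dtype=np.int64), np.empty(0)
    elec = np.repeat(np.arange(n), counts)
    times = rng.uniform(0.0, d, tot)
    accept = rng.uniform(0.0, 1.0, tot) * lam_max[elec] \
        < intensity_hz[elec, times.astype(np.int64)]
    return elec[accept], t0_ms + times[accept]


def _baseline_spikes(rate_hz: float, n: int, duration_ms: float,
                     rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    counts = rng.poisson(rate_hz * duration_ms / 1000.0, n)
    tot = int(counts.sum())
    elec = np.repeat(np.arange(n), counts)
    times = rng.uniform(0.0, duration_ms, tot)
    return elec, times


def _finalize_events(elecs: list[np.ndarray], times: list[np.ndarray]) -> pd.DataFrame:
    e = np.concatenate(elecs) if elecs else np.empty(0, dtype=np.int64)
    t = np.concatenate(times) if times else np.empty(0)
    t = np.round(t, TIME_DECIMALS)
    order = np.lexsort((t, e))
    return pd.DataFrame({"electrode": e[order].astype(np.int64), "time_ms": t[order]})


def _burst_onsets(rate_per_min: float, refractory_ms: float,
                  duration_ms: float, max_template_ms: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Renewal onsets: refractory gap plus an exponential waiting time.

    The exponential mean is calibrated so the realized mean rate equals the
    configured rate (interval mean = 60000/rate); onsets stop early enough
    for every burst to complete within the epoch.
    """
    if rate_per_min <= 0:
        return np.empty(0)
    mean_interval = 60e3 / rate_per_min
    exp_mean = mean_interval - refractory_ms
    if exp_mean <= 0:
        raise ValueError("burst rate incompatible with the refractory gap")
    onsets = []
    t = float(rng.exponential(exp_mean))
    limit = duration_ms - max_template_ms
    while t < limit:
        onsets.append(t)
        t += refractory_ms + rng.exponential(exp_mean)
    return np.asarray(onsets)


def simulate_recording(config: SimulationConfig,
                       geometry: ElectrodeGeometry | None = None,
                       epoch: str = "before"
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one spontaneous epoch.

    Returns ``(events, ground_truth)``: events with columns
    ``electrode, time_ms`` (sorted by electrode then time, 0.1 ms
    precision) and one ground-truth row per generated burst
    (``onset_ms, template, epoch, kind, site``).

    In the ``after`` epoch, stimulated templates appear only at their
    residual weight, and a fraction of the remaining bursts is *remapped*:
    they start from a stimulated template's initial-state region but then
    follow a random surviving template — the planted basin-reshaping
    effect.
    """
    if epoch not in ("before", "after", "control"):
        raise ValueError(f"unknown epoch {epoch!r}")
    geometry = geometry or make_geometry()
    rng = _epoch_rng(config.seed, epoch)
    duration_ms = config.epoch_duration_hours * 3.6e6
    max_t = max((t.duration_ms for t in config.templates), default=0.0)
    onsets = _burst_onsets(config.burst_rate_per_min, config.refractory_ms,
                           duration_ms, max_t, rng)
    if len(onsets) == 0 and config.burst_rate_per_min > 0:
        warnings.warn("epoch too short for a single burst; empty ground truth")

    weights = config.weights_for(epoch)
    elecs, times, gt_rows = [], [], []
    surviving = [t.template_id for t in config.templates
                 if t.template_id not in config.stimulated_templates]
    remap_p = config.remap_prob if epoch == "after" else 0.0
    for onset in onsets:
        remapped = False
        if (remap_p > 0 and config.stimulated_templates and len(surviving) >= 2
                and rng.uniform() < remap_p):
            # burst launched from a stimulated template's old initial-state
            # region: the flattened basin no longer pulls it onto the
            # pattern, so the burst wanders around the old pathway with
            # noise that never decays — same initial states, divergent
            # bursts
            src = config.templates[int(rng.choice(config.stimulated_templates))]
            degraded = replace(src, template_id=-1,
                               convergence_half_life_ms=config.disruption_half_life_ms)
            f = config.disruption_noise_factor
            lam = realization_intensity(
                degraded, geometry, rng, config.noise_scale * f,
                config.path_jitter_mm, config.gain_noise_sd,
                config.amp_jitter_sd / f,   # spatial disruption, stable amplitude
                noise_envelope="grow")      # same initial state, then diverge
            tid = -1
            remapped = True
        else:
            tid = int(rng.choice(len(config.templates), p=weights))
            tmpl = config.templates[tid]
            lam = realization_intensity(tmpl, geometry, rng, config.noise_scale,
                                        config.path_jitter_mm, config.gain_noise_sd,
                                        config.amp_jitter_sd)
        e, ts = _thin_spikes(lam, rng, onset)
        elecs.append(e)
        times.append(ts)
        gt_rows.append({"onset_ms": onset, "template": tid, "epoch": epoch,
                        "kind": "spontaneous", "site": -1, "remapped": remapped})

    e, ts = _baseline_spikes(config.baseline_hz, geometry.n_electrodes,
                             duration_ms, rng)
    elecs.append(e)
    times.append(ts)
    events = _finalize_events(elecs, times)
    gt = pd.DataFrame(gt_rows, columns=["onset_ms", "template", "epoch",
                                        "kind", "site", "remapped"])
    return events, gt


def simulate_evoked_session(config: SimulationConfig,
                            geometry: ElectrodeGeometry | None = None,
                            site_map: dict[int, int | None] | None = None,
                            epoch: str = "probe",
                            inject_artifacts: bool = False,
                            artifact_rate_hz: float = 200.0,
                            artifact_ms: float = 200.0,
                            noise_ramp: tuple[float, float] | None = None
                            ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a stimulation session over the mapped sites.

    ``site_map`` assigns each probed site id (1..20) a template id (robust
    site: every pulse converges to that template from the site's corner of
    state space) or ``None`` (non-robust: each pulse draws a random
    template at doubled realization noise).  Sites are probed one after the
    other, ``reps_per_site`` pulses each, ``isi_s`` apart.

    In ``epoch='after'`` sessions the realization-noise scale shrinks
    linearly across the session (default ramp 1.0 -> 0.3), modelling
    evoked responses growing more stereotyped; pass ``noise_ramp`` to
    override.  ``inject_artifacts`` adds dense events on the stimulating
    electrodes for ``artifact_ms`` after each pulse, to exercise masking.

    Returns ``(events, ground_truth, stim_log)``; the log has columns
    ``site, pulse_time_ms, e1..e6``.
    """
    geometry = geometry or make_geometry()
    sites = {s.site_id: s for s in define_sites(geometry)}
    if site_map is None:
        site_map = {sid: None for sid in sites}
    for sid in site_map:
        if sid not in sites:
            raise ValueError(f"site id {sid} outside 1..{len(sites)}")
    rng = _epoch_rng(config.seed, epoch if epoch in _EPOCH_CODES else "probe")
    if noise_ramp is None:
        noise_ramp = (1.0, 0.3) if epoch == "after" else (1.0, 1.0)

    isi_ms = config.isi_s * 1e3
    pulse_entries = []  # (pulse_time, site_id, rep_index)
    t = isi_ms
    for sid in sorted(site_map):
        for rep in range(config.reps_per_site):
            pulse_entries.append((t, sid, rep))
            t += isi_ms
    session_span = t

    elecs, times, gt_rows, log_rows = [], [], [], []
    for pulse_t, sid, rep in pulse_entries:
        site = sites[sid]
        # the ramp runs over each site's own stimulation course, so every
        # site's responses grow more stereotyped across its session
        frac = rep / max(config.reps_per_site - 1, 1)
        scale = config.noise_scale * (noise_ramp[0] + (noise_ramp[1] - noise_ramp[0]) * frac)
        mapped = site_map[sid]
        if mapped is None:
            tid = int(rng.integers(len(config.templates)))
            scale = scale * 2.0
        else:
            # the stimulus pins the trajectory into the mapped attractor's
            # basin, so evoked realizations are tighter than spontaneous ones
            tid = int(mapped)
            scale = scale * 0.7
        tmpl = config.templates[tid]
        centroid = geometry.coords[list(site.electrodes)].mean(axis=0)
        onset = pulse_t + config.latency_ms
        lam = realization_intensity(tmpl, geometry, rng, scale,
                                    config.path_jitter_mm, config.gain_noise_sd,
                                    config.amp_jitter_sd,
                                    start_center_mm=centroid)
        e, ts = _thin_spikes(lam, rng, onset)
        elecs.append(e)
        times.append(ts)
        if inject_artifacts:
            n_art = rng.poisson(artifact_rate_hz * artifact_ms / 1000.0,
                                len(site.electrodes))
            ae = np.repeat(np.asarray(site.electrodes), n_art)
            at = pulse_t + rng.uniform(0.0, artifact_ms, int(n_art.sum()))
            elecs.append(ae)
            times.append(at)
        gt_rows.append({"onset_ms": onset, "template": tid, "epoch": epoch,
                        "kind": "evoked", "site": sid, "remapped": False})
        log_rows.append({"site": sid, "pulse_time_ms": pulse_t,
                         **{f"e{i+1}": el for i, el in enumerate(site.electrodes)}})

    e, ts = _baseline_spikes(config.baseline_hz, geometry.n_electrodes,
                             session_span + 1e3, rng)
    elecs.append(e)
    times.append(ts)
    events = _finalize_events(elecs, times)
    gt = pd.DataFrame(gt_rows, columns=["onset_ms", "template", "epoch",
                                        "kind", "site", "remapped"])
    log = pd.DataFrame(log_rows)
    return events, gt, log
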