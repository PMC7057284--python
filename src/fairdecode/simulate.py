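"""Synthetic study generator with planted, behavior-linked neural signal.

Emulates a two-cohort proposer study (31 subjects: 19 + 12) playing mixed
ultimatum/dictator games against human and computer opponents, 12 trials per
(game x opponent) cell.  Each subject carries a latent selfishness in [0, 1]
that drives

* behavior -- the mean UG-DG offer gap grows linearly with selfishness (plus
  a constant cohort-2 offset reproducing the reported sample difference), and
  the social premium on offers against humans shrinks with selfishness, so
  prosocial subjects show the larger human-vs-computer dictator gap;
* brain -- trials add a condition-specific spatial pattern over a fixed
  signal region, with the UG/DG pattern separation scaled by an amplitude
  monotone in the subject's offer gap, convolved with the double-gamma HRF,
  on top of white noise and a slow cosine drift.

Ground truth (selfishness, amplitudes, the signal mask) is returned so
recovery can be tested.  Null studies (``signal_amplitude_max = 0``) drive
every downstream accuracy estimator to chance.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import behavior as behavior_mod
from .glm import BoldRun, TrialPatterns, double_gamma_hrf, validate_events, OFFER_GRID
from .volumes import MaskVolume

__all__ = [
    "SimConfig",
    "SyntheticTruth",
    "SubjectData",
    "StudyData",
    "simulate_offers",
    "expected_cell_means",
    "build_events",
    "simulate_bold",
    "generate_study",
    "generate_pattern_study",
]


@dataclass
class SimConfig:
    """Study-design and signal parameters of the generator.

    Amounts are euros, times seconds, amplitudes in the units of the
    simulated signal (arbitrary BOLD units at simulation, roughly t-units
    after estimation).  Defaults reproduce the emulated study design: 31
    subjects in cohorts of 19 and 12, 12 trials per (game x opponent) cell,
    TR 2 s, offers 0-14 in steps of 2.
    """

    n_subjects: int = 31
    cohort_sizes: tuple[int, int] = (19, 12)
    n_trials_per_cell: int = 12
    tr_s: float = 2.0
    grid_shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 3.5
    signal_amplitude_max: float = 0.45
    noise_sd: float = 1.0
    selfishness_range: tuple[float, float] = (0.0, 1.0)
    seed: int = 0
    # offer model
    ug_mean_eur: float = 10.0
    max_gap_eur: float = 8.0
    cohort2_gap_offset_eur: float = 2.0
    social_premium_max_eur: float = 4.0
    offer_noise_sd_eur: float = 1.5
    # trial timing (wait screen, decision phase, response window)
    wait_s: float = 8.0
    decision_s: float = 6.0
    response_s: float = 8.0
    run_padding_s: float = 20.0
    # noise structure
    drift_amplitude: float = 1.0
    drift_period_s: float = 192.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_cell < 1:
            raise ValueError("subject and trial counts must be >= 1")
        if sum(self.cohort_sizes) != self.n_subjects:
            raise ValueError("cohort sizes must sum to n_subjects")
        if min(self.cohort_sizes) < 1:
            raise ValueError("both cohorts need at least one subject")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        lo, hi = self.selfishness_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("selfishness_range must lie within [0, 1]")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.drift_period_s < 128:
            raise ValueError("drift period must be at least 128 s (slow drift)")

    @property
    def trial_length_s(self) -> float:
        return self.wait_s + self.decision_s + self.response_s

    @property
    def n_trials(self) -> int:
        return 4 * self.n_trials_per_cell

    @property
    def max_effective_gap_eur(self) -> float:
        return min(self.max_gap_eur + self.cohort2_gap_offset_eur, self.ug_mean_eur)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated study."""

    selfishness: np.ndarray           # per subject, in [0, 1]
    per_subject_amplitude: np.ndarray  # monotone in selfishness within cohort
    cohort: np.ndarray                # per subject, in {1, 2}
    signal_voxel_mask: np.ndarray     # 3-D binary
    expected_gap_eur: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __post_init__(self) -> None:
        if not np.all((self.selfishness >= 0) & (self.selfishness <= 1)):
            raise ValueError("selfishness must lie in [0, 1]")
        if not self.signal_voxel_mask.any():
            raise ValueError("signal mask must be nonempty")
        for c in (1, 2):
            sel = self.cohort == c
            if sel.sum() > 1:
                order = np.argsort(self.selfishness[sel], kind="stable")
                amp = self.per_subject_amplitude[sel][order]
                if np.any(np.diff(amp) < -1e-12):
                    raise ValueError("amplitude must be non-decreasing in selfishness")


@dataclass
class SubjectData:
    subject_id: str
    cohort: int
    selfishness: float
    amplitude: float
    events: pd.DataFrame
    bold: BoldRun | None = None
    patterns: TrialPatterns | None = None


@dataclass
class StudyData:
    config: SimConfig
    subjects: list[SubjectData]
    behavior: pd.DataFrame
    truth: SyntheticTruth
    masks: dict[str, MaskVolume]


def _cell_means(selfishness: float, config: SimConfig, gap_offset_eur: float) -> dict:
    """Noise-free mean offer per (game, opponent) cell for one subject."""
    gap = min(selfishness * config.max_gap_eur + gap_offset_eur, config.ug_mean_eur)
    premium = (1.0 - selfishness) * config.social_premium_max_eur
    ug_h = config.ug_mean_eur
    dg_h = ug_h - gap
    return {("UG", "human"): ug_h,
            ("DG", "human"): dg_h,
            ("UG", "computer"): max(ug_h - premium, 0.0),
            ("DG", "computer"): max(dg_h - premium, 0.0)}


def _round_to_grid(values: np.ndarray) -> np.ndarray:
    step = OFFER_GRID[1] - OFFER_GRID[0]
    snapped = np.rint(values / step) * step
    return np.clip(snapped, OFFER_GRID[0], OFFER_GRID[-1])


def simulate_offers(
    selfishness: float,
    n_trials_per_cell: int,
    noise_sd: float,
    rng_seed: int,
    config: SimConfig | None = None,
    gap_offset_eur: float = 0.0,
) -> pd.DataFrame:
    """Draw per-trial offers for all four (game, opponent) cells.

    Offers are the subject's noise-free cell mean plus Gaussian noise,
    snapped to the discrete 0-14 euro grid in steps of 2.  The expected
    UG-DG gap on human trials is ``selfishness * max_gap_eur`` (+ the cohort
    offset); the social premium subtracted on computer trials is
    ``(1 - selfishness) * social_premium_max_eur``, so prosocial subjects
    show the larger human-vs-computer dictator gap.
    """
    if not 0.0 <= selfishness <= 1.0:
        raise ValueError(f"selfishness must lie in [0, 1], got {selfishness}")
    if n_trials_per_cell < 1:
        raise ValueError("n_trials_per_cell must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    config = config or SimConfig()
    rng = np.random.default_rng(rng_seed)
    means = _cell_means(selfishness, config, gap_offset_eur)
    rows = []
    for (game, opp), mu in means.items():
        raw = mu + rng.normal(0.0, noise_sd, size=n_trials_per_cell) \
            if noise_sd > 0 else np.full(n_trials_per_cell, mu)
        for offer in _round_to_grid(raw):
            rows.append({"game": game, "opponent": opp, "offer": float(offer)})
    return pd.DataFrame(rows)


def expected_cell_means(
    selfishness: float,
    noise_sd: float,
    config: SimConfig | None = None,
    gap_offset_eur: float = 0.0,
) -> dict:
    """Closed-form expected offer per cell under grid snapping and clipping.

    The offer is round-to-nearest on the even grid after adding Gaussian
    noise, so the expectation is a sum of grid values weighted by Gaussian
    bin probabilities (edge bins open-ended).
    """
    from scipy.stats import norm

    config = config or SimConfig()
    means = _cell_means(selfishness, config, gap_offset_eur)
    step = OFFER_GRID[1] - OFFER_GRID[0]
    out = {}
    for cell, mu in means.items():
        if noise_sd == 0:
            out[cell] = float(_round_to_grid(np.array([mu]))[0])
            continue
        total = 0.0
        for g in OFFER_GRID:
            lo = -np.inf if g == OFFER_GRID[0] else (g - step / 2 - mu) / noise_sd
            hi = np.inf if g == OFFER_GRID[-1] else (g + step / 2 - mu) / noise_sd
            total += g * (norm.cdf(hi) - norm.cdf(lo))
        out[cell] = total
    return out


def build_events(
    offers: pd.DataFrame,
    config: SimConfig,
    rng_seed: int,
) -> pd.DataFrame:
    """Arrange offers into a timed event table.

    Trial order is a seeded shuffle of the 4 x n cell structure.  Each trial
    occupies wait + decision + response seconds; the keypress falls uniformly
    within the decision phase, so the 6-s pre-response epoch reaches back
    into the wait screen with trial-specific jitter.
    """
    rng = np.random.default_rng(rng_seed)
    order = rng.permutation(len(offers))
    shuffled = offers.iloc[order].reset_index(drop=True)
    spacing = config.trial_length_s
    onsets = np.arange(len(shuffled)) * spacing
    rts = onsets + config.wait_s + rng.uniform(1.0, config.decision_s,
                                               size=len(shuffled))
    events = pd.DataFrame({
        "onset": onsets,
        "duration": np.full(len(shuffled), config.decision_s),
        "game": shuffled["game"],
        "opponent": shuffled["opponent"],
        "response_time": rts,
        "offer": shuffled["offer"],
    })
    return validate_events(events)


def _study_masks(config: SimConfig) -> dict[str, MaskVolume]:
    """Brain (ellipsoid), signal ('ToM-like'), null ('control-like') and
    white-matter-like fixture masks on the study grid."""
    nx, ny, nz = config.grid_shape
    ix = np.indices(config.grid_shape).astype(float)
    center = (np.asarray(config.grid_shape) - 1) / 2.0
    radii = np.asarray(config.grid_shape) / 2.0 - 0.5
    dist = sum(((ix[d] - center[d]) / radii[d]) ** 2 for d in range(3))
    brain = dist <= 1.0

    def block(lo_frac, size_frac):
        lo = (np.asarray(config.grid_shape) * np.asarray(lo_frac)).astype(int)
        hi = lo + np.maximum((np.asarray(config.grid_shape) *
                              np.asarray(size_frac)).astype(int), 2)
        m = np.zeros(config.grid_shape, dtype=bool)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return m & brain

    # signal and control blocks sit at opposite ends of the ellipsoid so
    # searchlight spheres centered in one cannot reach the other
    signal = block((0.20, 0.20, 0.38), (0.25, 0.25, 0.25))
    control = block((0.62, 0.62, 0.38), (0.25, 0.25, 0.25)) & ~signal
    wm = block((0.44, 0.30, 0.62), (0.12, 0.12, 0.12)) & ~signal & ~control
    for name, m in (("signal", signal), ("control", control), ("wm", wm)):
        if not m.any():
            raise ValueError(f"grid {config.grid_shape} too small for the {name} mask")
    affine = np.diag([config.voxel_size_mm] * 3 + [1.0])
    return {"brain": MaskVolume(brain, affine, name="brain"),
            "tom_like": MaskVolume(signal, affine, name="tom_like"),
            "control_like": MaskVolume(control, affine, name="control_like"),
            "wm_like": MaskVolume(wm, affine, name="wm_like")}


def _condition_patterns(
    signal_mask: np.ndarray,
    rng: np.random.Generator,
    smoothness_vox: float = 1.2,
) -> dict[str, np.ndarray]:
    """Fixed random unit-norm common/difference vectors over signal voxels.

    The UG pattern is ``common + diff`` and the DG pattern ``common - diff``
    (each scaled by the subject amplitude at use), so the between-condition
    separation is tunable while both conditions evoke a response.  The
    fields are drawn as spatially correlated Gaussian noise (correlation
    length ``smoothness_vox``), mimicking the spatial coherence of real
    activation patterns; a spatially white pattern would be destroyed by the
    smoothing the searchlight pipeline applies.
    """
    from scipy.ndimage import gaussian_filter

    n_sig = int(signal_mask.sum())
    out = {}
    fields = []
    for _ in range(2):
        field = rng.standard_normal(signal_mask.shape)
        if smoothness_vox > 0:
            field = gaussian_filter(field, smoothness_vox, mode="wrap")
        vec = field[signal_mask]
        fields.append(vec * np.sqrt(n_sig) / np.linalg.norm(vec))
    common, diff = fields
    out["UG"] = common + diff
    out["DG"] = common - diff
    return out


def simulate_bold(
    events: pd.DataFrame,
    amplitude: float,
    patterns: dict[str, np.ndarray],
    masks: dict[str, MaskVolume],
    config: SimConfig,
    rng_seed: int,
    epoch_s: float = 6.0,
    noise_sd: float | None = None,
    drift_amplitude: float | None = None,
) -> BoldRun:
    """Synthesize one subject's 4-D BOLD run.

    Each trial adds ``amplitude x`` its game's spatial pattern over the
    signal voxels, modulated in time by the double-gamma-convolved boxcar
    over the 6-s pre-keypress epoch; white Gaussian noise (``noise_sd``) and
    a slow cosine drift are added everywhere inside the grid.  Trial epochs
    must be disjoint and inside the run.  ``noise_sd`` / ``drift_amplitude``
    override the config values (e.g. 0 for noise-free construction checks).
    """
    events = validate_events(events)
    rng = np.random.default_rng(rng_seed)
    run_dur = float(events["onset"].iloc[-1]) + config.trial_length_s \
        + config.run_padding_s if len(events) else config.run_padding_s
    n_vol = int(np.ceil(run_dur / config.tr_s))

    epochs = np.column_stack([
        np.maximum(events["onset"].to_numpy(float),
                   events["response_time"].to_numpy(float) - epoch_s),
        events["response_time"].to_numpy(float)]) if len(events) else np.zeros((0, 2))
    for i in range(1, len(epochs)):
        if epochs[i, 0] < epochs[i - 1, 1]:
            raise ValueError(
                f"trial epochs overlap: trial {i - 1} ends at {epochs[i - 1, 1]:.1f} s "
                f"but trial {i} starts at {epochs[i, 0]:.1f} s")
    if len(epochs) and epochs[-1, 1] > n_vol * config.tr_s:
        raise ValueError("events do not fit within the run duration")

    dt = 0.1
    hrf = double_gamma_hrf(dt)
    n_fine = int(np.ceil(n_vol * config.tr_s / dt)) + 1
    fine_t = np.arange(n_fine) * dt
    vol_idx = np.rint(np.arange(n_vol) * config.tr_s / dt).astype(int)

    signal_mask = masks["tom_like"].data
    sig_where = np.argwhere(signal_mask)
    data = np.zeros(config.grid_shape + (n_vol,), dtype=float)

    if amplitude != 0:
        for i, trial in events.iterrows():
            start, stop = epochs[i]
            boxcar = ((fine_t >= start) & (fine_t < stop)).astype(float)
            reg = np.convolve(boxcar, hrf)[:n_fine][vol_idx] * dt
            pattern = amplitude * patterns[str(trial["game"])]
            data[sig_where[:, 0], sig_where[:, 1], sig_where[:, 2], :] += \
                np.outer(pattern, reg)

    noise_sd = config.noise_sd if noise_sd is None else noise_sd
    drift_amp = config.drift_amplitude if drift_amplitude is None else drift_amplitude
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=data.shape)
    if drift_amp > 0:
        t = np.arange(n_vol) * config.tr_s
        phase = rng.uniform(0, 2 * np.pi)
        amp_vox = rng.uniform(0, drift_amp, size=config.grid_shape)
        data += amp_vox[..., None] * np.cos(
            2 * np.pi * t / config.drift_period_s + phase)[None, None, None, :]
    return BoldRun(data, config.tr_s, masks["brain"].data,
                   affine=masks["brain"].affine)


def _draw_subjects(config: SimConfig, rng: np.random.Generator):
    """Selfishness spread over the configured range; seeded cohort labels."""
    lo, hi = config.selfishness_range
    selfishness = np.linspace(lo, hi, config.n_subjects) if config.n_subjects > 1 \
        else np.array([(lo + hi) / 2])
    cohort = np.array([1] * config.cohort_sizes[0] + [2] * config.cohort_sizes[1])
    rng.shuffle(cohort)
    offsets = np.where(cohort == 2, config.cohort2_gap_offset_eur, 0.0)
    gaps = np.minimum(selfishness * config.max_gap_eur + offsets, config.ug_mean_eur)
    denom = config.max_effective_gap_eur or 1.0
    amplitude = config.signal_amplitude_max * gaps / denom
    return selfishness, cohort, offsets, gaps, amplitude


def _spawn_seeds(seed: int, n: int) -> np.ndarray:
    """Independent child seeds below 2**31, deterministic in ``seed``."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=n)


def _regressor_norm(events: pd.DataFrame, config: SimConfig, epoch_s: float = 6.0) -> float:
    """RMS norm of the HRF-convolved epoch regressors at the TR sampling.

    Used to express the planted signal in t-units: a BOLD pattern of
    amplitude a yields a trial beta of a with standard error
    noise_sd / ||regressor||, hence a t-contrast of a ||regressor|| / noise_sd.
    """
    from .glm import _trial_regressors

    run_dur = float(events["onset"].iloc[-1]) + config.trial_length_s \
        + config.run_padding_s
    n_vol = int(np.ceil(run_dur / config.tr_s))
    cols = _trial_regressors(events, n_vol, config.tr_s, epoch_s, 0.1, None)
    return float(np.sqrt(np.mean(np.sum(cols**2, axis=0))))


def generate_study(config: SimConfig | None = None, include_bold: bool = True) -> StudyData:
    """Generate the full synthetic study (events, behavior, BOLD, truth).

    Deterministic given ``config.seed``.  With ``include_bold=False`` only
    events and behavior are produced (cheap, for behavioral analyses).
    ``truth.per_subject_amplitude`` is the planted UG/DG t-contrast scale;
    BOLD signal amplitudes are converted via the regressor norm so the
    estimated t-patterns carry that contrast irrespective of run timing.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    selfishness, cohort, offsets, gaps, amplitude = _draw_subjects(config, rng)
    masks = _study_masks(config)
    patterns = _condition_patterns(masks["tom_like"].data, rng)
    seeds = _spawn_seeds(rng.integers(0, 2**31 - 1), 2 * config.n_subjects)

    subjects: list[SubjectData] = []
    events_by_subject: dict[str, pd.DataFrame] = {}
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:02d}"
        offers = simulate_offers(selfishness[i], config.n_trials_per_cell,
                                 config.offer_noise_sd_eur, int(seeds[2 * i]),
                                 config=config, gap_offset_eur=offsets[i])
        events = build_events(offers, config, int(seeds[2 * i]))
        bold = None
        if include_bold:
            bold_amp = amplitude[i] * config.noise_sd / _regressor_norm(events, config)
            bold = simulate_bold(events, bold_amp, patterns, masks,
                                 config, int(seeds[2 * i + 1]))
        subjects.append(SubjectData(sid, int(cohort[i]), float(selfishness[i]),
                                    float(amplitude[i]), events, bold=bold))
        events_by_subject[sid] = events
    behavior = behavior_mod.offer_differences(
        events_by_subject, cohorts={s.subject_id: s.cohort for s in subjects})
    truth = SyntheticTruth(selfishness, amplitude, cohort,
                           masks["tom_like"].data, expected_gap_eur=gaps)
    return StudyData(config, subjects, behavior, truth, masks)


def generate_pattern_study(config: SimConfig | None = None) -> StudyData:
    """Generate a study at the trial-pattern level, skipping BOLD synthesis.

    Trial t-maps are drawn directly as white noise plus the amplitude-scaled
    condition pattern over the signal voxels -- the same planted structure
    the GLM would estimate, at a fraction of the cost.  Used for the
    many-replicate calibration and recovery analyses.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    selfishness, cohort, offsets, gaps, amplitude = _draw_subjects(config, rng)
    masks = _study_masks(config)
    patterns = _condition_patterns(masks["tom_like"].data, rng)
    seeds = _spawn_seeds(rng.integers(0, 2**31 - 1), 2 * config.n_subjects)

    brain = masks["brain"].data
    coords = np.argwhere(brain)
    lut = np.full(config.grid_shape, -1, dtype=int)
    lut[brain] = np.arange(len(coords))
    sig_cols = lut[masks["tom_like"].data]

    subjects: list[SubjectData] = []
    events_by_subject: dict[str, pd.DataFrame] = {}
    for i in range(config.n_subjects):
        sid = f"sub-{i + 1:02d}"
        offers = simulate_offers(selfishness[i], config.n_trials_per_cell,
                                 config.offer_noise_sd_eur, int(seeds[2 * i]),
                                 config=config, gap_offset_eur=offsets[i])
        events = build_events(offers, config, int(seeds[2 * i]))
        sub_rng = np.random.default_rng(int(seeds[2 * i + 1]))
        values = sub_rng.normal(0.0, config.noise_sd,
                                size=(len(events), len(coords)))
        if amplitude[i] != 0:
            for game in ("UG", "DG"):
                rows = (events["game"] == game).to_numpy()
                values[np.ix_(rows, sig_cols)] += amplitude[i] * patterns[game]
        tp = TrialPatterns(values,
                           events[["game", "opponent", "response_time", "offer"]],
                           coords, config.grid_shape, subject_id=sid,
                           cohort=int(cohort[i]))
        subjects.append(SubjectData(sid, int(cohort[i]), float(selfishness[i]),
                                    float(amplitude[i]), events, patterns=tp))
        events_by_subject[sid] = events
    behavior = behavior_mod.offer_differences(
        events_by_subject, cohorts={s.subject_id: s.cohort for s in subjects})
    truth = SyntheticTruth(selfishness, amplitude, cohort,
                           masks["tom_like"].data, expected_gap_eur=gaps)
    return StudyData(config, subjects, behavior, truth, masks)
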