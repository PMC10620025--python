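"""Synthetic two-group BOLD-like studies with known ground truth.

The generator emulates the structure of a resting-state case/control sample:
each subject is an ROI x time matrix of autocorrelated signals built from
shared latent AR(1) sources plus white measurement noise, z-scored per
region. Scan geometry defaults to 180 time points at a 2 s sampling interval.

Group differences are injected through *informative pairs*. For each pair
(i, j), every subject receives extra fluctuations of equal amplitude in both
regions, so the two groups are variance-matched and no amplitude side channel
exists; the groups differ only in whether those fluctuations are shared:

* ``strength`` effect: group B's extra fluctuations in i and j are one common
  source (synchronous); group A's are independent. Both a correlation-based
  and a warping-based connectivity measure can see the resulting coupling
  difference.
* ``lag`` effect: group B's common source enters region j delayed by τ
  samples (circular shift, τ within the warping band). The injected sources
  are temporally white at the sampling resolution, so a one-sample lag makes
  the shared fluctuations invisible to zero-lag Pearson correlation while
  DTW, which realigns the series inside its band, still registers the
  coupling. This operationalizes the observation that inter-regional
  hemodynamic lags (up to about ±2 s) bias correlation-based connectivity.

Circular shifts keep the series length and stationarity; an optional
double-gamma hemodynamic-response convolution is available as a robustness
knob (it low-passes and partially re-synchronizes lags, so it is off by
default). A separate helper draws pure-noise feature tables for studying
optimistic bias in cross-validation, where the true accuracy is 0.5 by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal as sps
from scipy import stats

from .connectivity import FeatureTable, StudySet, SubjectRecord

__all__ = [
    "SimConfig",
    "SimulatedStudy",
    "simulate_ar_sources",
    "hrf_kernel",
    "hrf_convolve",
    "simulate_study",
    "pure_noise_dataset",
]

EFFECT_KINDS = ("strength", "lag")


@dataclass(frozen=True)
class SimConfig:
    """Full parameterization of the synthetic two-group generator.

    Parameters
    ----------
    n_per_group : int
        Subjects per group; group A is labeled 0, group B 1.
    n_rois, n_timepoints, dt : int, int, float
        Scan geometry. Defaults: 180 time points at 2 s.
    ar_coef : float in [0, 1)
        AR(1) coefficient of the latent background sources (marginal
        variance 1).
    n_latent_sources : int
        Number of shared background sources; loadings are drawn once per
        study so the background correlation structure is common to all
        subjects.
    loading_scale : float
        Scale of the Gaussian loadings onto background sources.
    informative_pairs : tuple of (i, j, kind, effect)
        ``kind`` is ``"strength"`` (effect = coupling amplitude) or ``"lag"``
        (effect = lag in samples; amplitude taken from ``pair_amplitude``).
    pair_amplitude : float
        Amplitude of the extra per-pair fluctuations (both groups receive
        this amplitude; only sharedness/lag differs).
    noise_sd : float
        White measurement noise standard deviation.
    hrf : bool
        Convolve region signals with a canonical double-gamma kernel before
        adding noise.
    seed : int
        Master seed; generation is fully deterministic given the config.
    """

    n_per_group: int = 20
    n_rois: int = 20
    n_timepoints: int = 180
    dt: float = 2.0
    ar_coef: float = 0.3
    n_latent_sources: int = 5
    loading_scale: float = 0.5
    informative_pairs: tuple = ()
    pair_amplitude: float = 2.0
    noise_sd: float = 1.0
    hrf: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.n_per_group < 1 or self.n_rois < 2 or self.n_timepoints < 4:
            raise ValueError("need n_per_group >= 1, n_rois >= 2, n_timepoints >= 4")
        if not self.dt > 0:
            raise ValueError("dt must be > 0")
        for pair in self.informative_pairs:
            i, j, kind, effect = pair
            if kind not in EFFECT_KINDS:
                raise ValueError(f"effect kind must be one of {EFFECT_KINDS}")
            if not (0 <= i < self.n_rois and 0 <= j < self.n_rois and i != j):
                raise ValueError(f"pair ({i}, {j}) references invalid ROI indices")
            if kind == "lag":
                tau = int(effect)
                if abs(tau) > self.n_timepoints // 4:
                    raise ValueError(
                        f"lag {tau} samples exceeds T/4 = {self.n_timepoints // 4}; "
                        "circular shift would be degenerate"
                    )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["informative_pairs"] = [list(p) for p in self.informative_pairs]
        return d


@dataclass
class SimulatedStudy:
    """A generated study with its ground-truth informative pairs."""

    study: StudySet
    truth: tuple
    config: SimConfig


def simulate_ar_sources(k: int, T: int, rho: float, seed) -> np.ndarray:
    """k stationary AR(1) rows of length T with marginal variance 1.

    Innovations have variance 1 - rho^2 and the initial state is drawn from
    the stationary marginal, so every sample has unit variance. ``seed`` may
    be an integer or a ``numpy.random.Generator``.
    """
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    e = rng.standard_normal((k, T))
    if rho == 0:
        return e
    # x_t = rho x_{t-1} + sqrt(1-rho^2) e_t with x_0 = e_0 ~ N(0, 1)
    scaled = np.sqrt(1.0 - rho**2) * e
    scaled[:, 0] = e[:, 0]
    return sps.lfilter([1.0], [1.0, -rho], scaled, axis=-1)


def hrf_kernel(dt: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at interval dt.

    Peak at 6 s, undershoot at 16 s, undershoot-to-peak ratio 1/6; the kernel
    spans ``duration`` seconds and is normalized to unit sum of its positive
    lobe scale (peak gamma integrates to 1 before the undershoot subtraction).
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    t = np.arange(0, duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, a=7.0, scale=1.0)  # mode (a-1)*scale = 6 s
    undershoot = stats.gamma.pdf(t, a=17.0, scale=1.0)  # mode 16 s
    return peak - undershoot / 6.0


def hrf_convolve(x, dt: float, standardize: bool = True) -> np.ndarray:
    """Convolve a signal with the canonical kernel, truncated to the input
    length; optionally re-standardize to mean 0, unit variance. A zero input
    stays zero."""
    x = np.asarray(x, dtype=float)
    out = np.convolve(x, hrf_kernel(dt))[: x.size]
    if standardize:
        sd = out.std()
        if sd > 0:
            out = (out - out.mean()) / sd
    return out


def _inject_pairs(data: np.ndarray, config: SimConfig, group: int, rng) -> None:
    """Add per-pair fluctuations in place (variance-matched across groups)."""
    T = config.n_timepoints
    for i, j, kind, effect in config.informative_pairs:
        if kind == "strength":
            amp, tau = float(effect), 0
        else:
            amp, tau = config.pair_amplitude, int(effect)
        if group == 1:
            u = rng.standard_normal(T)
            data[i] += amp * u
            data[j] += amp * np.roll(u, tau)
        else:
            data[i] += amp * rng.standard_normal(T)
            data[j] += amp * rng.standard_normal(T)


def simulate_study(config: SimConfig) -> SimulatedStudy:
    """Generate a labeled two-group study from a config.

    Each region's series is a loading mix of shared AR(1) background sources
    plus pair injections and white noise, optionally HRF-convolved, then
    z-scored (population sd). Subjects are emitted group A first, then
    group B; byte-identical outputs follow from identical configs.
    """
    rng = np.random.default_rng(config.seed)
    loadings_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    L = config.loading_scale * loadings_rng.standard_normal(
        (config.n_rois, config.n_latent_sources)
    )
    records = []
    for group in (0, 1):
        for s in range(config.n_per_group):
            sources = simulate_ar_sources(
                config.n_latent_sources, config.n_timepoints, config.ar_coef, rng
            )
            data = L @ sources
            _inject_pairs(data, config, group, rng)
            if config.hrf:
                data = np.vstack([hrf_convolve(row, config.dt, standardize=False) for row in data])
            data = data + config.noise_sd * rng.standard_normal(data.shape)
            mean = data.mean(axis=1, keepdims=True)
            sd = data.std(axis=1, keepdims=True)
            data = (data - mean) / sd
            records.append(
                SubjectRecord(
                    subject_id=f"sub-{group}{s:03d}",
                    data=data,
                    label=group,
                    dt=config.dt,
                )
            )
    study = StudySet(records=records)
    return SimulatedStudy(study=study, truth=tuple(config.informative_pairs), config=config)


def pure_noise_dataset(n: int, p: int, seed: int) -> FeatureTable:
    """An n x p table of i.i.d. standard-normal features with balanced labels
    drawn independently of the features, so any classifier's true accuracy
    is 0.5. Used for null-calibration and CV-bias experiments."""
    if n % 2:
        raise ValueError("n must be even for balanced labels")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    labels = np.repeat([0, 1], n // 2)
    rng.shuffle(labels)
    width = len(str(p))
    return FeatureTable(
        X=X,
        feature_names=[f"f{i + 1:0{width}d}" for i in range(p)],
        labels=labels,
        subject_ids=[f"noise-{i:04d}" for i in range(n)],
        measure="noise",
        meta={"generator": "pure_noise", "seed": seed},
    )
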