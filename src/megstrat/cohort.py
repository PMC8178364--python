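"""Synthetic multi-group cohorts of region-of-interest (ROI) time series.

The study design this package targets compares four participant groups
(PTSD, trauma-exposed controls, mTBI, non-trauma controls) on source-space
"virtual sensor" recordings: per subject, 90 ROI time series segmented into
10 s epochs. Raw clinical recordings of this kind are not publicly
deposited, so this module generates cohorts with *known* discriminative
structure, making every downstream stage (spectral features, envelope
connectivity, screening, selection, evaluation) testable end to end.

Signal model, per ROI channel and epoch::

    x(t) = noise_scale * pink(t)  +  sum_b  a_b * e_b(t) * sin(2*pi*f_b*t + phi)

where ``pink`` is 1/f^alpha background noise, ``a_b`` the band amplitude,
``f_b`` the band centre frequency, ``phi`` a random phase per
(epoch, region, band), and ``e_b(t)`` a slowly varying positive random
envelope. Two kinds of ground-truth effect can be planted:

* ``power`` effects multiply ``a_b`` in target ROIs for target groups;
* ``edge`` effects make two ROIs' band envelopes share a common slow
  modulation, so their amplitude envelope correlation rises with the
  coupling coefficient (identical envelopes at coupling 1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .bands import CANONICAL_BANDS, BandDefinition

GROUPS: tuple[str, ...] = ("PTSD", "TC", "mTBI", "NTC")

#: Study-scale default group sizes (n = 101).
DEFAULT_GROUP_SIZES: dict[str, int] = {"PTSD": 24, "TC": 27, "mTBI": 27, "NTC": 23}


class ConfigurationError(ValueError):
    """Raised when a cohort configuration or effect specification is invalid."""


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort.

    Attributes
    ----------
    n_per_group : dict
        Subject count per group label; every listed group must be non-empty.
    n_regions : int
        Number of ROIs (90 emulates an AAL-style parcellation).
    fs : float
        Sampling rate in Hz; must exceed twice the highest band edge used.
    epoch_len : float
        Epoch length in seconds; ``epoch_len * fs`` must be an integer.
    n_epochs : int
        Epochs per subject.
    noise_exponent : float
        Power-law slope alpha of the 1/f^alpha background (power spectrum).
    noise_scale : float
        Standard deviation of the background noise (0 disables it).
    base_band_amplitudes : dict
        Band name -> oscillation amplitude; bands absent from the map carry
        no oscillation.
    env_depth : float
        Modulation depth of the slow random envelopes (0 gives constant
        unit envelopes).
    amp_jitter_subject : float
        Log-normal sigma of a per-subject global amplitude factor applied
        to the whole recording — individuals differ in overall source
        power (0 disables).
    amp_jitter_region : float
        Log-normal sigma of independent per-(band, region) oscillation
        amplitude factors — regional band power varies between subjects
        beyond any group effect (0 disables).
    coupling_jitter : float
        SD of per-subject jitter on each planted edge's coupling
        coefficient (clipped to [0, 1]) — individuals differ in
        connectivity strength, not only in mean level (0 disables).
    global_coupling : float
        Mean of a per-subject global envelope co-modulation shared by all
        regions (arousal-like slow fluctuations). Raises baseline AEC for
        every pair and varies between subjects with SD
        ``global_coupling_sd``; 0 disables.
    global_coupling_sd : float
        Between-subject SD of the global co-modulation coefficient.
    bands : tuple of BandDefinition
        The bands the generator knows about (defaults to the canonical 7).
    seed : int
        Master seed; all per-subject randomness derives from it.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    n_regions: int = 90
    fs: float = 600.0
    epoch_len: float = 10.0
    n_epochs: int = 12
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    base_band_amplitudes: dict[str, float] = field(
        default_factory=lambda: {
            "delta": 1.0,
            "theta": 0.8,
            "alpha": 0.7,
            "beta": 0.5,
            "low_gamma_1": 0.3,
            "low_gamma_2": 0.2,
            "high_gamma": 0.15,
        }
    )
    env_depth: float = 0.5
    amp_jitter_subject: float = 0.2
    amp_jitter_region: float = 0.3
    coupling_jitter: float = 0.25
    global_coupling: float = 0.15
    global_coupling_sd: float = 0.10
    bands: tuple[BandDefinition, ...] = CANONICAL_BANDS
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.epoch_len * self.fs))

    @property
    def band_map(self) -> dict[str, BandDefinition]:
        return {b.name: b for b in self.bands}

    def validate(self) -> None:
        if not self.n_per_group:
            raise ConfigurationError("n_per_group is empty")
        for g, n in self.n_per_group.items():
            if n < 1:
                raise ConfigurationError(f"group {g!r} has {n} subjects; need >= 1")
        if self.n_regions < 2:
            raise ConfigurationError("need at least 2 regions")
        if self.n_epochs < 1 or self.epoch_len <= 0:
            raise ConfigurationError("need positive epoch_len and n_epochs")
        if abs(self.epoch_len * self.fs - round(self.epoch_len * self.fs)) > 1e-9:
            raise ConfigurationError("epoch_len * fs must be an integer sample count")
        used = [b for b in self.bands if self.base_band_amplitudes.get(b.name, 0) > 0]
        if used:
            hi = max(b.hi for b in used)
            if self.fs <= 2 * hi:
                raise ConfigurationError(
                    f"fs={self.fs} Hz cannot resolve band edge {hi} Hz (need fs > {2 * hi})"
                )
        unknown = set(self.base_band_amplitudes) - set(self.band_map)
        if unknown:
            raise ConfigurationError(f"amplitudes reference unknown bands: {sorted(unknown)}")


@dataclass(frozen=True)
class EffectSpec:
    """One planted group effect: a power elevation or an envelope coupling.

    ``kind='power'``: ``regions`` is a single ROI index and ``magnitude``
    multiplies the band amplitude (so band *power* scales by magnitude**2).
    ``kind='edge'``: ``regions`` is an ordered pair ``(i, j)`` with ``i < j``
    and ``magnitude`` is a coupling coefficient in [0, 1] equal to the
    target correlation of the two ROIs' slow band envelopes.
    """

    kind: str
    band: str
    regions: int | tuple[int, int]
    groups: tuple[str, ...]
    magnitude: float

    def validate(self, config: CohortConfig) -> None:
        if self.kind not in ("power", "edge"):
            raise ConfigurationError(f"unknown effect kind {self.kind!r}")
        if self.band not in config.band_map:
            raise ConfigurationError(f"effect references unknown band {self.band!r}")
        if self.magnitude < 0:
            raise ConfigurationError("effect magnitude must be >= 0")
        if self.kind == "power":
            r = self.regions
            if not isinstance(r, (int, np.integer)) or not 0 <= r < config.n_regions:
                raise ConfigurationError(f"invalid power effect ROI {r!r}")
        else:
            if self.magnitude > 1:
                raise ConfigurationError("edge coupling must be in [0, 1]")
            try:
                i, j = self.regions  # type: ignore[misc]
            except TypeError:
                raise ConfigurationError("edge effect needs an (i, j) pair") from None
            if not (0 <= i < j < config.n_regions):
                raise ConfigurationError(f"invalid edge pair {(i, j)} (need 0 <= i < j < n)")
        for g in self.groups:
            if g not in config.n_per_group:
                raise ConfigurationError(f"effect targets unknown group {g!r}")


@dataclass
class SubjectRecording:
    """One subject's epoch-segmented multi-ROI recording.

    ``data`` has shape ``(n_epochs, n_regions, n_samples)``.
    """

    subject_id: str
    group: str
    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_epochs, n_regions, n_samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# generation internals


def _pink_noise(rng: np.random.Generator, shape: tuple[int, ...], n: int,
                fs: float, exponent: float, scale: float) -> np.ndarray:
    """1/f^exponent noise along the last axis, standardised to sd = scale."""
    if scale == 0:
        return np.zeros(shape + (n,))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(shape + (freqs.size,))
            + 1j * rng.standard_normal(shape + (freqs.size,))) * amp
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return scale * x / sd


def _slow_process(rng: np.random.Generator, shape: tuple[int, ...],
                  n: int, fs: float, slow_fs: float = 2.0) -> np.ndarray:
    """Standardised slowly varying Gaussian process (spectral content < 1 Hz).

    Drawn as white noise on a coarse ``slow_fs`` grid and linearly
    interpolated up to the sampling grid, then re-standardised per series.
    """
    n_slow = max(int(np.ceil(n / fs * slow_fs)) + 2, 4)
    coarse = rng.standard_normal(shape + (n_slow,))
    t = np.arange(n) / fs * slow_fs
    idx = np.minimum(t.astype(int), n_slow - 2)
    frac = t - idx
    z = coarse[..., idx] * (1 - frac) + coarse[..., idx + 1] * frac
    z = z - z.mean(axis=-1, keepdims=True)
    sd = z.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return z / sd


def generate_subject(config: CohortConfig, group: str,
                     effects: list[EffectSpec] | tuple[EffectSpec, ...] = (),
                     seed: int = 0, subject_id: str | None = None) -> SubjectRecording:
    """Generate one subject's recording under the planted-effect model.

    Determinism: identical ``(config, group, effects, seed)`` give a
    bit-identical recording.
    """
    config.validate()
    for eff in effects:
        eff.validate(config)
    if group not in config.n_per_group:
        raise ConfigurationError(f"unknown group {group!r}")

    rng = np.random.default_rng(seed)
    E, R, N = config.n_epochs, config.n_regions, config.n_samples
    t = np.arange(N) / config.fs

    global_factor = float(np.exp(config.amp_jitter_subject
                                 * rng.standard_normal()))
    c_global = float(np.clip(config.global_coupling
                             + config.global_coupling_sd * rng.standard_normal(),
                             0.0, 0.9)) if config.global_coupling > 0 else 0.0
    # per-subject realised coupling of each planted edge effect
    c_edges = {
        k: float(np.clip(eff.magnitude
                         + config.coupling_jitter * rng.standard_normal(),
                         0.0, 1.0))
        for k, eff in enumerate(effects) if eff.kind == "edge"
    }
    data = _pink_noise(rng, (E, R), N, config.fs,
                       config.noise_exponent, config.noise_scale)

    active = [(name, a) for name, a in config.base_band_amplitudes.items() if a > 0]
    band_map = config.band_map
    for name, base_amp in active:
        band = band_map[name]
        region_factor = np.exp(config.amp_jitter_region
                               * rng.standard_normal(R))
        # slow envelope processes, one per (epoch, region), plus an
        # arousal-like global co-modulation shared by all regions
        z = _slow_process(rng, (E, R), N, config.fs)
        if c_global > 0:
            g0 = _slow_process(rng, (E,), N, config.fs)
            z = (np.sqrt(c_global) * g0[:, None, :]
                 + np.sqrt(1.0 - c_global) * z)
        shared_cache: dict[tuple[int, int], np.ndarray] = {}
        amp = np.full(R, base_amp)
        for k, eff in enumerate(effects):
            if eff.band != name or group not in eff.groups:
                continue
            if eff.kind == "power":
                amp[eff.regions] *= eff.magnitude
            else:
                i, j = eff.regions  # type: ignore[misc]
                key = (i, j)
                if key not in shared_cache:
                    shared_cache[key] = _slow_process(rng, (E,), N, config.fs)
                g = shared_cache[key]
                c = c_edges[k] if config.coupling_jitter > 0 else eff.magnitude
                for r in (i, j):
                    z[:, r, :] = np.sqrt(c) * g + np.sqrt(1.0 - c) * z[:, r, :]
        env = np.maximum(1.0 + config.env_depth * z, 0.0)
        phase = rng.uniform(0, 2 * np.pi, size=(E, R, 1))
        carrier = np.sin(2 * np.pi * band.center * t[None, None, :] + phase)
        data += (amp * region_factor)[None, :, None] * env * carrier

    data *= global_factor
    sid = subject_id or f"{group}_s{seed}"
    return SubjectRecording(subject_id=sid, group=group, data=data, fs=config.fs)


def subject_seeds(config: CohortConfig, n: int) -> list[int]:
    """Deterministic per-subject seeds derived from the master seed."""
    ss = np.random.SeedSequence(config.seed)
    return [int(s.generate_state(1)[0] & 0x7FFFFFFF) for s in ss.spawn(n)]


def generate_cohort(config: CohortConfig,
                    effects: list[EffectSpec] | tuple[EffectSpec, ...] = ()
                    ) -> tuple[list[SubjectRecording], dict]:
    """Generate a full cohort plus its ground-truth effect map.

    Returns ``(recordings, ground_truth)`` where ``ground_truth`` is a
    JSON-serialisable record of the planted effects and configuration, used
    by recovery tests to check that selection finds what was planted.
    """
    config.validate()
    for eff in effects:
        eff.validate(config)

    order: list[tuple[str, int]] = []
    for g in config.n_per_group:
        for k in range(config.n_per_group[g]):
            order.append((g, k))
    seeds = subject_seeds(config, len(order))

    recordings = []
    for (g, k), s in zip(order, seeds):
        rec = generate_subject(config, g, effects, seed=s,
                               subject_id=f"{g}_{k:02d}")
        recordings.append(rec)

    ground_truth = {
        "seed": config.seed,
        "n_per_group": dict(config.n_per_group),
        "effects": [
            {
                "kind": e.kind,
                "band": e.band,
                "regions": list(e.regions) if e.kind == "edge" else int(e.regions),
                "groups": list(e.groups),
                "magnitude": e.magnitude,
            }
            for e in effects
        ],
    }
    return recordings, ground_truth


# ---------------------------------------------------------------------------
# persistence


def save_cohort_hdf5(path, recordings: list[SubjectRecording],
                     ground_truth: dict | None = None) -> None:
    """Write a cohort to one HDF5 container (/subjects/<id>/data)."""
    import h5py

    with h5py.File(path, "w") as f:
        grp = f.create_group("subjects")
        for rec in recordings:
            d = grp.create_group(rec.subject_id)
            d.create_dataset("data", data=rec.data, compression="gzip")
            d.attrs["group"] = rec.group
            d.attrs["fs"] = rec.fs
        if ground_truth is not None:
            f.attrs["ground_truth"] = json.dumps(ground_truth)


def load_cohort_hdf5(path) -> tuple[list[SubjectRecording], dict | None]:
    import h5py

    recordings = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f["subjects"]):
            d = f["subjects"][sid]
            recordings.append(SubjectRecording(
                subject_id=sid, group=str(d.attrs["group"]),
                data=d["data"][...], fs=float(d.attrs["fs"])))
        gt = json.loads(f.attrs["ground_truth"]) if "ground_truth" in f.attrs else None
    return recordings, gt


def export_subject_csv(rec: SubjectRecording, path, epoch: int = 0) -> None:
    """Debug export: one epoch as a regions x samples CSV."""
    np.savetxt(path, rec.data[epoch], delimiter=",")
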