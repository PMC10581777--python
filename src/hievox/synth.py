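"""Synthetic marmoset-like vocalizations with controllable caller structure.

Generates the three call types used throughout the package — trills
(sinusoidal frequency modulation within 5–8 kHz, 0.3–0.8 s), phees
(narrowband slow-drift tones within 6–8 kHz, 0.5–2 s) and food calls
(~0.05 s downsweeps from 10 to 6 kHz) — and whole "colonies" of callers.
Each simulated individual carries a stable parameter signature (fundamental
offset, duration scaling, modulation rate/depth, sweep rate) drawn from
sex-conditional distributions, so downstream classifiers have a recoverable
sex cue and per-individual identity cues. Same-sex twin pairs can be planted
by interpolating two individuals' signatures toward each other.

None of this aims at perceptual realism: calls are tonal FM signals with a
raised-cosine onset/offset envelope plus white Gaussian noise at a configured
SNR. That is enough structure for feature extraction, balancing and
classification to be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import windows

from .core import CALL_TYPES, SEXES, CallRecord, Waveform

# Nominal acoustics per call type. Frequencies in Hz, durations in seconds.
CALL_NOMINALS: dict[str, dict] = {
    "trill": {
        "f0_hz": 6500.0,          # FM carrier, centre of the 5-8 kHz band
        "band_hz": (5000.0, 8000.0),
        "duration_s": (0.3, 0.8),
        "fm_rate_hz": 30.0,       # sinusoidal pitch-modulation rate
        "fm_depth_hz": 1200.0,    # keeps 6500 +/- depth inside the band
    },
    "phee": {
        "f0_hz": 7000.0,
        "band_hz": (6000.0, 8000.0),
        "duration_s": (0.5, 2.0),
        "drift_hz": 250.0,        # slow within-call frequency drift span
        "drift_rate_hz": 1.5,
    },
    "food_call": {
        "f0_hz": 10_000.0,        # sweep start
        "band_hz": (6000.0, 10_000.0),
        "duration_s": (0.05, 0.05),
        "sweep_span_hz": 4000.0,  # 10 kHz -> 6 kHz downsweep
    },
}

# Between-individual standard deviations of the signature parameters.
# f0 offsets are additive Hz; the *_scale parameters are log-normal
# (sd given on the log scale) so they stay strictly positive.
SIGNATURE_SD = {
    "f0_offset_hz": 150.0,
    "duration_scale": 0.12,
    "fm_rate_offset_hz": 3.0,
    "fm_depth_scale": 0.15,
    "sweep_rate_scale": 0.10,
}

# Within-individual (call-to-call) jitter standard deviations.
DEFAULT_JITTER_SD = {
    "f0_offset_hz": 40.0,
    "duration_scale": 0.05,
    "fm_rate_offset_hz": 1.0,
    "fm_depth_scale": 0.05,
    "sweep_rate_scale": 0.05,
}

#: Default difference between female and male mean f0 offsets (Hz): females
#: are shifted up and males down by half this amount in every call type.
#: 500 Hz is ~3x the within-sex per-call f0 spread, so a single call carries
#: a strongly recoverable sex cue — the regime in which a sex-first
#: hierarchical classifier is expected to help.
DEFAULT_SEX_EFFECT_HZ = 500.0

_PARAM_NAMES = tuple(SIGNATURE_SD)


@dataclass(frozen=True)
class IndividualProfile:
    """A caller's stable acoustic signature.

    ``base_offsets`` maps call type to the five signature parameters;
    ``jitter_sd`` gives the per-call jitter applied around them.
    """

    individual_id: str
    sex: str
    base_offsets: dict[str, dict[str, float]]
    jitter_sd: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_JITTER_SD)
    )

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        for ct, params in self.base_offsets.items():
            for name in ("duration_scale", "fm_depth_scale", "sweep_rate_scale"):
                if params[name] <= 0:
                    raise ValueError(
                        f"{name} must be strictly positive "
                        f"(individual {self.individual_id!r}, call type {ct!r})"
                    )


@dataclass(frozen=True)
class ColonySpec:
    """Design of a synthetic colony.

    ``calls_per_type`` values may be a single int (same count for every
    individual) or a sequence of per-individual counts (females first, in id
    order) to create class imbalance. ``twin_pairs`` plants same-sex pairs
    whose signatures are interpolated toward each other by ``similarity``
    (1.0 makes the signatures identical).
    """

    n_females: int
    n_males: int
    calls_per_type: dict = field(
        default_factory=lambda: {ct: 10 for ct in CALL_TYPES}
    )
    twin_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    noise_snr_db: float = 20.0
    sample_rate_hz: int = 62_500
    seed: int = 0
    sex_effect_hz: float = DEFAULT_SEX_EFFECT_HZ
    signature_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_females < 0 or self.n_males < 0:
            raise ValueError("individual counts must be >= 0")
        for ct in self.calls_per_type:
            if ct not in CALL_TYPES:
                raise ValueError(f"unknown call type {ct!r}")
        for a, b, sim in self.twin_pairs:
            if not 0.0 <= sim <= 1.0:
                raise ValueError(f"twin similarity must be in [0, 1], got {sim}")

    @property
    def individual_ids(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(self.n_females)] + [
            f"M{i + 1:02d}" for i in range(self.n_males)
        ]


def _as_rng(rng_state) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _truncated_normal(
    rng: np.random.Generator, sd: float, lo: float, hi: float
) -> float:
    """Zero-mean normal draw truncated to [lo, hi] by redraw."""
    if sd == 0:
        return 0.0
    for _ in range(100):
        x = rng.normal(0.0, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(rng.normal(0.0, sd), lo, hi))


def make_profile(
    sex: str,
    rng_state,
    individual_id: str = "ind",
    *,
    sex_effect_hz: float = DEFAULT_SEX_EFFECT_HZ,
    signature_scale: float = 1.0,
    jitter_sd: dict[str, float] | None = None,
) -> IndividualProfile:
    """Draw one caller signature from the sex-conditional distributions.

    Females get ``+sex_effect_hz/2`` and males ``-sex_effect_hz/2`` on the
    mean f0 offset of every call type; all other parameters are drawn from
    sex-independent distributions. ``signature_scale`` multiplies the
    between-individual spread (0 removes individual identity cues).
    ``sex_effect_hz = 0`` removes the sex cue, making the two sexes'
    distributions identical.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    rng = _as_rng(rng_state)
    f0_shift = (0.5 if sex == "F" else -0.5) * sex_effect_hz
    base: dict[str, dict[str, float]] = {}
    for ct in CALL_TYPES:
        band_lo, band_hi = CALL_NOMINALS[ct]["band_hz"]
        half_band = 0.5 * (band_hi - band_lo)
        sd_f0 = SIGNATURE_SD["f0_offset_hz"] * signature_scale
        # truncate so nominal frequencies stay inside the call band
        f0_offset = f0_shift + _truncated_normal(
            rng, sd_f0, -half_band + abs(f0_shift), half_band - abs(f0_shift)
        )
        params = {
            "f0_offset_hz": f0_offset,
            "duration_scale": float(
                np.exp(rng.normal(0.0, SIGNATURE_SD["duration_scale"] * signature_scale))
            ),
            "fm_rate_offset_hz": float(
                rng.normal(0.0, SIGNATURE_SD["fm_rate_offset_hz"] * signature_scale)
            ),
            "fm_depth_scale": float(
                np.exp(rng.normal(0.0, SIGNATURE_SD["fm_depth_scale"] * signature_scale))
            ),
            "sweep_rate_scale": float(
                np.exp(rng.normal(0.0, SIGNATURE_SD["sweep_rate_scale"] * signature_scale))
            ),
        }
        base[ct] = params
    return IndividualProfile(
        individual_id=individual_id,
        sex=sex,
        base_offsets=base,
        jitter_sd=dict(jitter_sd) if jitter_sd is not None else dict(DEFAULT_JITTER_SD),
    )


def _envelope(n: int, onset_frac: float = 0.1) -> np.ndarray:
    """Raised-cosine onset/offset covering ``onset_frac`` of the call each."""
    return windows.tukey(n, alpha=2.0 * onset_frac)


def _add_noise(y: np.ndarray, snr_db: float, rng: np.random.Generator) -> np.ndarray:
    if not np.isfinite(snr_db):
        return y
    p_signal = float(np.mean(y**2))
    p_noise = p_signal / (10.0 ** (snr_db / 10.0))
    return y + rng.normal(0.0, np.sqrt(p_noise), size=y.size)


def synth_call(
    call_type: str,
    profile: IndividualProfile,
    rng_state,
    *,
    rate_hz: int = 62_500,
    noise_snr_db: float = 20.0,
) -> Waveform:
    """Synthesize one call of ``call_type`` from a caller's signature.

    The instantaneous-frequency track is built per call type, phase-integrated
    into a tone, shaped by a raised-cosine envelope, mixed with white noise at
    ``noise_snr_db`` and peak-normalized.
    """
    if call_type not in CALL_TYPES:
        raise ValueError(
            f"unknown call_type {call_type!r}; expected one of {CALL_TYPES}"
        )
    nominal = CALL_NOMINALS[call_type]
    base = profile.base_offsets[call_type]
    jit = profile.jitter_sd
    rng = _as_rng(rng_state)

    # per-call parameter draws around the individual's signature
    f0_offset = base["f0_offset_hz"] + rng.normal(0.0, jit["f0_offset_hz"])
    duration_scale = base["duration_scale"] * np.exp(
        rng.normal(0.0, jit["duration_scale"])
    )
    lo_d, hi_d = nominal["duration_s"]
    duration = rng.uniform(lo_d, hi_d) * duration_scale
    n = max(int(round(duration * rate_hz)), 16)
    t = np.arange(n) / rate_hz

    if call_type == "trill":
        fm_rate = max(
            nominal["fm_rate_hz"]
            + base["fm_rate_offset_hz"]
            + rng.normal(0.0, jit["fm_rate_offset_hz"]),
            1.0,
        )
        fm_depth = nominal["fm_depth_hz"] * base["fm_depth_scale"] * np.exp(
            rng.normal(0.0, jit["fm_depth_scale"])
        )
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        freq = nominal["f0_hz"] + f0_offset + fm_depth * np.sin(
            2.0 * np.pi * fm_rate * t + phase0
        )
    elif call_type == "phee":
        drift_rate = max(
            nominal["drift_rate_hz"] * (1.0 + 0.1 * base["fm_rate_offset_hz"]), 0.1
        )
        drift = nominal["drift_hz"] * base["fm_depth_scale"]
        phase0 = rng.uniform(0.0, 2.0 * np.pi)
        glide = rng.uniform(-0.5, 0.5) * drift
        freq = (
            nominal["f0_hz"]
            + f0_offset
            + drift * 0.5 * np.sin(2.0 * np.pi * drift_rate * t + phase0)
            + glide * (t / t[-1] - 0.5)
        )
    else:  # food_call: linear downsweep 10 -> 6 kHz (rate scaled per caller)
        sweep_scale = base["sweep_rate_scale"] * np.exp(
            rng.normal(0.0, jit["sweep_rate_scale"])
        )
        span = nominal["sweep_span_hz"] * sweep_scale
        start = nominal["f0_hz"] + f0_offset
        freq = start - span * (t / duration)

    nyquist = rate_hz / 2.0
    if np.max(freq) >= nyquist:
        raise ValueError(
            f"instantaneous frequency {np.max(freq):.0f} Hz reaches the "
            f"Nyquist limit {nyquist:.0f} Hz; raise the sample rate"
        )
    freq = np.maximum(freq, 50.0)

    phase = 2.0 * np.pi * np.cumsum(freq) / rate_hz
    y = np.sin(phase) * _envelope(n)
    y = _add_noise(y, noise_snr_db, rng)
    peak = np.max(np.abs(y))
    if peak > 0:
        y = 0.98 * y / peak
    return Waveform(samples=y, rate_hz=rate_hz)


def _interpolate_twins(
    profiles: dict[str, IndividualProfile],
    twin_pairs: list[tuple[str, str, float]],
) -> dict[str, IndividualProfile]:
    out = dict(profiles)
    for id_a, id_b, sim in twin_pairs:
        if id_a not in out or id_b not in out:
            raise ValueError(f"twin pair ({id_a!r}, {id_b!r}) references unknown ids")
        pa, pb = out[id_a], out[id_b]
        if pa.sex != pb.sex:
            raise ValueError(
                f"twin pair ({id_a!r}, {id_b!r}) crosses sexes "
                f"({pa.sex} vs {pb.sex}); twins must be same-sex"
            )
        new_a, new_b = {}, {}
        for ct in pa.base_offsets:
            a, b = pa.base_offsets[ct], pb.base_offsets[ct]
            # move each endpoint sim/2 of the way toward the other;
            # sim = 1 collapses both onto the midpoint
            new_a[ct] = {k: a[k] + 0.5 * sim * (b[k] - a[k]) for k in a}
            new_b[ct] = {k: b[k] + 0.5 * sim * (a[k] - b[k]) for k in b}
        out[id_a] = replace(pa, base_offsets=new_a)
        out[id_b] = replace(pb, base_offsets=new_b)
    return out


def _counts_for(spec: ColonySpec, call_type: str) -> list[int]:
    ids = spec.individual_ids
    raw = spec.calls_per_type.get(call_type, 0)
    if np.isscalar(raw):
        counts = [int(raw)] * len(ids)
    else:
        counts = [int(c) for c in raw]
        if len(counts) != len(ids):
            raise ValueError(
                f"calls_per_type[{call_type!r}] has {len(counts)} entries for "
                f"{len(ids)} individuals"
            )
    if any(c < 0 for c in counts):
        raise ValueError("call counts must be >= 0")
    return counts


def generate_colony(spec: ColonySpec) -> tuple[list[Waveform], list[CallRecord]]:
    """Generate every call of a colony plus its ground-truth records.

    One signature per individual (drawn from sex-conditional distributions,
    then twin-interpolated), then ``calls_per_type`` calls per individual and
    type. Deterministic: the same spec (including seed) reproduces the same
    waveforms bit for bit.
    """
    ids = spec.individual_ids
    root = np.random.SeedSequence(spec.seed)
    profile_seeds, call_seed = root.spawn(2)
    ind_seeds = profile_seeds.spawn(len(ids))
    profiles: dict[str, IndividualProfile] = {}
    for ind_id, seed in zip(ids, ind_seeds):
        sex = "F" if ind_id.startswith("F") else "M"
        profiles[ind_id] = make_profile(
            sex,
            np.random.default_rng(seed),
            individual_id=ind_id,
            sex_effect_hz=spec.sex_effect_hz,
            signature_scale=spec.signature_scale,
        )
    profiles = _interpolate_twins(profiles, spec.twin_pairs)

    waveforms: list[Waveform] = []
    records: list[CallRecord] = []
    call_rng_seq = call_seed.spawn(len(CALL_TYPES) * len(ids))
    seq_iter = iter(call_rng_seq)
    for call_type in CALL_TYPES:
        counts = _counts_for(spec, call_type)
        for ind_id, n_calls in zip(ids, counts):
            rng = np.random.default_rng(next(seq_iter))
            for i in range(n_calls):
                w = synth_call(
                    call_type,
                    profiles[ind_id],
                    rng,
                    rate_hz=spec.sample_rate_hz,
                    noise_snr_db=spec.noise_snr_db,
                )
                records.append(
                    CallRecord(
                        call_id=f"{ind_id}_{call_type}_{i:04d}",
                        file="",
                        start_s=0.0,
                        end_s=w.duration_s,
                        call_type=call_type,
                        individual_id=ind_id,
                        sex=profiles[ind_id].sex,
                    )
                )
                waveforms.append(w)
    return waveforms, records


def colony_profiles(spec: ColonySpec) -> dict[str, IndividualProfile]:
    """The signatures :func:`generate_colony` would use (twin-adjusted)."""
    ids = spec.individual_ids
    root = np.random.SeedSequence(spec.seed)
    profile_seeds, _ = root.spawn(2)
    ind_seeds = profile_seeds.spawn(len(ids))
    profiles = {}
    for ind_id, seed in zip(ids, ind_seeds):
        sex = "F" if ind_id.startswith("F") else "M"
        profiles[ind_id] = make_profile(
            sex,
            np.random.default_rng(seed),
            individual_id=ind_id,
            sex_effect_hz=spec.sex_effect_hz,
            signature_scale=spec.signature_scale,
        )
    return _interpolate_twins(profiles, spec.twin_pairs)
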