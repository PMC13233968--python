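"""Seeded synthetic pediatric ECG cohorts with known QT/RR/QTc labels.

The generator emulates the marginal statistics of a large pediatric
hospital ECG population: heart rate is lognormal with an age-dependent
location (median 96 bpm overall, IQR roughly 77-126), and the Bazett QTc
follows a two-component mixture — a normal core around 421 ms plus a small
long-QT tail — whose defaults were fitted once so that the population
median is ~424 ms and the prevalence of QTc >= 460/470/500 ms is
13.1%/9.0%/3.0%.

Waveforms are rendered per beat from a sum-of-Gaussians P-QRS-T template
(one bump each for the P, Q, R, S and T deflections), with lead-specific
amplitude scaling over the 11 recorded leads (I, II, V1-V7, V3R, V4R).
The T bump is placed so that the tangent-method T offset lands exactly
``true_qt_ms`` after the template's Q onset, which makes the generator an
oracle for the median-beat QT measurer.  White noise and sinusoidal
baseline wander are added on top.

A "noisy oracle" surrogate predictor (truth + bias + proportional bias +
Gaussian noise) stands in for a trained regressor so that calibration and
evaluation are testable in seconds.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np

from .qtcore import DEFAULT_FS, bazett_qtc

__all__ = [
    "LEADS",
    "GeneratorParams",
    "SubjectProfile",
    "ECGRecord",
    "NoisyOracleParams",
    "InfeasibleLabelError",
    "sample_cohort",
    "synthesize_ecg",
    "generate_cohort",
    "noisy_oracle_predict",
    "labels_frame",
    "save_records_hdf5",
    "load_records_hdf5",
]

#: fixed lead order of the waveform columns
LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6", "V7", "V3R", "V4R")

#: relative R-wave amplitude per lead (dimensionless scale on the template)
LEAD_AMPLITUDE = {
    "I": 0.70, "II": 1.00, "V1": 0.50, "V2": 0.90, "V3": 1.10, "V4": 1.20,
    "V5": 1.00, "V6": 0.80, "V7": 0.60, "V3R": 0.45, "V4R": 0.40,
}

#: age bins used for fairness strata (years; right-open)
AGE_BINS = (
    ("newborn", 0.0, 1.0 / 12.0),
    ("infant", 1.0 / 12.0, 1.0),
    ("toddler", 1.0, 5.0),
    ("school_age", 5.0, 11.0),
    ("adolescent", 11.0, 18.0001),
)

#: heart-rate multiplier by age bin relative to the cohort-median HR.
#: Typical pediatric resting rates fall from ~140 bpm in newborns to
#: ~75 bpm in adolescents; multipliers are normalised so the cohort
#: median stays at ``hr_log_median_bpm`` under the default age mix.
AGE_HR_MULTIPLIER = {
    "newborn": 1.58, "infant": 1.35, "toddler": 1.19,
    "school_age": 0.99, "adolescent": 0.81,
}

RACE_PROBS = {
    "white": 0.523, "black": 0.253, "other": 0.188, "asian": 0.027,
    "unknown": 0.009,
}

#: age quartiles of the cohort (years): 25/50/75th percentiles
AGE_QUARTILES = (1.4, 8.8, 14.2)
AGE_MAX = 18.0


def age_bin_of(age_years: float) -> str:
    for name, lo, hi in AGE_BINS:
        if lo <= age_years < hi:
            return name
    raise ValueError(f"age {age_years} outside 0-18 years")


@dataclass(frozen=True)
class SubjectProfile:
    patient_id: str
    age_years: float
    sex: str
    race: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.age_years <= 18.0:
            raise ValueError("age_years must be within 0-18")
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")

    @property
    def age_bin(self) -> str:
        return age_bin_of(self.age_years)


@dataclass(frozen=True)
class GeneratorParams:
    """Cohort-level generator settings.

    The QTc mixture and heart-rate defaults are frozen constants chosen to
    reproduce the target population: QTc median ~424 ms (IQR 403-445) and
    long-QT prevalence 13.1%/9.0%/3.0% at 460/470/500 ms.
    """

    n_records: int = 1000
    seed: int = 0
    # heart rate: lognormal around an age-dependent median
    hr_log_median_bpm: float = 96.0
    hr_log_sd: float = 0.25
    age_hr_coupling: bool = True
    # QTc population mixture (ms)
    qtc_core_mean_ms: float = 421.1
    qtc_core_sd_ms: float = 27.8
    tail_weight: float = 0.0555
    tail_shift_ms: float = 79.0
    tail_sd_ms: float = 18.0
    # within-record RR variability
    rr_cv: float = 0.05
    # waveform realism
    noise_sd_mv: float = 0.01
    wander_amp_mv: float = 0.05
    wander_freq_hz: float = 0.25
    # demographics
    sex_probs: dict = field(default_factory=lambda: {"male": 0.5, "female": 0.5})
    race_probs: dict = field(default_factory=lambda: dict(RACE_PROBS))
    fs: float = DEFAULT_FS
    duration_s: float = 10.0

    def __post_init__(self) -> None:
        if self.n_records < 0:
            raise ValueError("n_records must be nonnegative")
        for name in ("hr_log_sd", "qtc_core_sd_ms", "tail_sd_ms", "rr_cv",
                     "noise_sd_mv", "wander_amp_mv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.tail_weight <= 1.0:
            raise ValueError("tail_weight must lie in [0, 1]")
        if self.hr_log_median_bpm <= 0:
            raise ValueError("hr_log_median_bpm must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass(frozen=True)
class ECGRecord:
    waveform: np.ndarray  # (n_samples, 11), mV
    subject: SubjectProfile
    true_qt_ms: float
    true_mean_rr_ms: float
    true_qtc_ms: float
    beat_onsets: np.ndarray  # R-peak sample indices
    fs: float = DEFAULT_FS

    def __post_init__(self) -> None:
        if self.waveform.ndim != 2 or self.waveform.shape[1] != len(LEADS):
            raise ValueError("waveform must be (n_samples, 11)")
        expected = bazett_qtc(self.true_qt_ms, self.true_mean_rr_ms)
        if abs(expected - self.true_qtc_ms) > 0.01:
            raise ValueError("true_qtc_ms violates the Bazett identity")
        onsets = np.asarray(self.beat_onsets)
        if onsets.size and (np.any(np.diff(onsets) <= 0)
                            or onsets[0] < 0
                            or onsets[-1] >= self.waveform.shape[0]):
            raise ValueError("beat_onsets must be strictly increasing indices "
                             "within the record")


@dataclass(frozen=True)
class NoisyOracleParams:
    """Surrogate predictor: truth + bias + slope*(truth - 424) + noise."""

    bias_ms: float = 0.0
    noise_sd_ms: float = 18.0
    slope: float = 0.0
    seed: int = 0
    center_ms: float = 424.0

    def __post_init__(self) -> None:
        if self.noise_sd_ms < 0:
            raise ValueError("noise_sd_ms must be nonnegative")


class InfeasibleLabelError(ValueError):
    """Requested QT does not fit inside the shortest RR interval."""


# ---------------------------------------------------------------------------
# label sampling
# ---------------------------------------------------------------------------

def _sample_ages(rng, n):
    """Ages matching the cohort quartiles (1.4 / 8.8 / 14.2 y) by a
    mixture of uniforms over the inter-quartile segments."""
    edges = np.array([0.0, *AGE_QUARTILES, AGE_MAX])
    seg = rng.integers(0, 4, size=n)
    u = rng.random(n)
    return edges[seg] + u * (edges[seg + 1] - edges[seg])


def _sample_qtc(rng, p: GeneratorParams, n):
    tail = rng.random(n) < p.tail_weight
    core = rng.normal(p.qtc_core_mean_ms, p.qtc_core_sd_ms, size=n)
    shifted = rng.normal(p.qtc_core_mean_ms + p.tail_shift_ms, p.tail_sd_ms,
                         size=n)
    qtc = np.where(tail, shifted, core)
    # physiologic floor: QTc below ~200 ms does not occur
    return np.clip(qtc, 200.0, None)


def sample_cohort(params: GeneratorParams):
    """Draw per-record labels: (SubjectProfile, true_qt_ms, rr_sequence_ms).

    QTc is drawn from the two-component mixture, heart rate from the
    age-coupled lognormal, and ``true_qt_ms = QTc * sqrt(RR)`` with RR the
    record's generative mean RR.  Where the implied QT would not fit into
    the RR interval (very fast rate with a long QTc), the mean RR is
    lengthened to the shortest feasible value so every label is
    renderable.  The within-record RR sequence is i.i.d. around the mean
    with coefficient of variation ``rr_cv`` (truncated at +-3 sd) and spans
    at least the record duration.  Deterministic given ``params.seed``.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n = p.n_records
    ages = _sample_ages(rng, n)
    sexes = rng.choice(list(p.sex_probs), size=n,
                       p=np.array(list(p.sex_probs.values()), dtype=float)
                       / sum(p.sex_probs.values()))
    races = rng.choice(list(p.race_probs), size=n,
                       p=np.array(list(p.race_probs.values()), dtype=float)
                       / sum(p.race_probs.values()))
    if p.age_hr_coupling:
        mult = np.array([AGE_HR_MULTIPLIER[age_bin_of(a)] for a in ages])
    else:
        mult = np.ones(n)
    hr = p.hr_log_median_bpm * mult * np.exp(rng.normal(0.0, p.hr_log_sd, n))
    hr = np.clip(hr, 40.0, 230.0)
    rr_mean = 60000.0 / hr
    qtc = _sample_qtc(rng, p, n)
    qt = qtc * np.sqrt(rr_mean / 1000.0)
    # feasibility: QT (plus room for the next QRS) must fit in the shortest
    # expected RR; lengthen mean RR where needed (keeps QTc as drawn)
    margin = 1.0 - 3.5 * p.rr_cv
    bad = qt + 80.0 > rr_mean * margin
    if np.any(bad):
        # solve qtc*sqrt(rr) + 80 = rr*margin for rr (take the larger root)
        for i in np.flatnonzero(bad):
            a = qtc[i] / np.sqrt(1000.0)
            rr = ((a + np.sqrt(a * a + 4.0 * margin * 80.0)) / (2 * margin)) ** 2
            rr_mean[i] = rr * 1.001
        qt = qtc * np.sqrt(rr_mean / 1000.0)

    need_ms = p.duration_s * 1000.0 + 800.0
    out = []
    for i in range(n):
        profile = SubjectProfile(
            patient_id=f"P{i:06d}", age_years=float(ages[i]),
            sex=str(sexes[i]), race=str(races[i]),
        )
        n_beats = int(np.ceil(need_ms / rr_mean[i])) + 2
        jitter = np.clip(rng.normal(0.0, p.rr_cv, n_beats), -3 * p.rr_cv,
                         3 * p.rr_cv)
        rr_seq = rr_mean[i] * (1.0 + jitter)
        # renormalise so the realised mean RR equals the generative mean;
        # keeps the Bazett identity exact on the stored labels
        rr_seq *= rr_mean[i] / rr_seq.mean()
        out.append((profile, float(qt[i]), rr_seq))
    return out


# ---------------------------------------------------------------------------
# waveform synthesis
# ---------------------------------------------------------------------------

# Gaussian bump parameters (center_ms rel. to R, sigma_ms, amplitude_mv)
_QRS_BUMPS = ((-25.0, 8.0, -0.10), (0.0, 12.0, 1.00), (30.0, 9.0, -0.15))
_P_AMP, _P_SIGMA = 0.12, 20.0
_T_AMP = 0.30


def _t_sigma(qt_ms: float) -> float:
    return float(np.clip(0.11 * qt_ms, 28.0, 50.0))


def _gauss(t, c, s, a):
    return a * np.exp(-0.5 * ((t - c) / s) ** 2)


@functools.lru_cache(maxsize=1)
def template_q_onset_ms(rel_thresh=0.02, sustain_ms=8.0) -> float:
    """Q onset of the analytic QRS template, located by the same rule the
    measurer uses (|dV/dt| above ``rel_thresh`` of the peak QRS slope,
    sustained ``sustain_ms``), evaluated on a dense 0.1 ms grid."""
    t = np.arange(-90.0, 60.0, 0.1)
    v = sum(_gauss(t, c, s, a) for c, s, a in _QRS_BUMPS)
    deriv = np.gradient(v, t)
    thresh = rel_thresh * np.max(np.abs(deriv))
    above = np.abs(deriv) >= thresh
    need = int(round(sustain_ms / 0.1))
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= need:
            return float(t[i - need + 1])
    raise RuntimeError("template Q onset not found")


def beat_template(t_ms, qt_ms, p_center_ms, rr_ms=None):
    """Evaluate the unit-amplitude P-QRS-T template at times ``t_ms``
    relative to the R peak.  The T bump is centred so its tangent-method
    offset equals ``qt_ms`` after the template Q onset.

    At fast rates with long repolarisation the P wave runs into the
    preceding beat's T wave; the template mimics the resulting P-on-T merge
    by fading the P amplitude as the gap between the previous T offset and
    the P wave closes.
    """
    sig_t = _t_sigma(qt_ms)
    q_on = template_q_onset_ms()
    t_center = q_on + qt_ms - 2.0 * sig_t
    p_amp = _P_AMP
    if rr_ms is not None:
        room = rr_ms + p_center_ms - (q_on + qt_ms)
        p_amp = _P_AMP * float(np.clip(room / 80.0, 0.0, 1.0))
    v = sum(_gauss(t_ms, c, s, a) for c, s, a in _QRS_BUMPS)
    v = v + _gauss(t_ms, p_center_ms, _P_SIGMA, p_amp)
    v = v + _gauss(t_ms, t_center, sig_t, _T_AMP)
    return v


def synthesize_ecg(subject_labels, params: GeneratorParams, rng=None):
    """Render one labelled record into a (n_samples, 11) waveform.

    ``subject_labels`` is a ``(SubjectProfile, true_qt_ms, rr_sequence_ms)``
    triple as produced by :func:`sample_cohort`.
    """
    profile, qt_ms, rr_seq = subject_labels
    rr_seq = np.asarray(rr_seq, dtype=float)
    if np.any(rr_seq <= 0):
        raise ValueError("rr_sequence must be positive")
    if qt_ms >= float(np.min(rr_seq)):
        raise InfeasibleLabelError(
            f"QT {qt_ms:.1f} ms >= shortest RR {np.min(rr_seq):.1f} ms")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    p = params
    n = p.n_samples
    t_grid = np.arange(n) * 1000.0 / p.fs  # ms
    rr_mean = float(np.mean(rr_seq))
    p_center = -min(160.0, 0.38 * rr_mean)

    r_times = np.concatenate([[0.45 * rr_seq[0]], 0.45 * rr_seq[0]
                              + np.cumsum(rr_seq[:-1])])
    r_times = r_times[r_times < t_grid[-1] + 400.0]
    base = np.zeros(n)
    half_span = 450.0 + qt_ms  # template support half-width, ms
    for rt in r_times:
        lo = max(0, int((rt - half_span) * p.fs / 1000.0))
        hi = min(n, int((rt + half_span) * p.fs / 1000.0) + 1)
        if hi <= lo:
            continue
        base[lo:hi] += beat_template(t_grid[lo:hi] - rt, qt_ms, p_center,
                                     rr_ms=rr_mean)

    amps = np.array([LEAD_AMPLITUDE[l] for l in LEADS])
    wave = base[:, None] * amps[None, :]
    if p.wander_amp_mv > 0:
        phase = rng.uniform(0, 2 * np.pi, size=len(LEADS))
        wave = wave + p.wander_amp_mv * np.sin(
            2 * np.pi * p.wander_freq_hz * t_grid[:, None] / 1000.0
            + phase[None, :])
    if p.noise_sd_mv > 0:
        wave = wave + rng.normal(0.0, p.noise_sd_mv, size=wave.shape)

    onsets = np.round(r_times * p.fs / 1000.0).astype(int)
    onsets = onsets[(onsets >= 0) & (onsets < n)]
    qtc = bazett_qtc(qt_ms, rr_mean)
    return ECGRecord(
        waveform=wave.astype(np.float64), subject=profile,
        true_qt_ms=float(qt_ms), true_mean_rr_ms=rr_mean,
        true_qtc_ms=float(qtc), beat_onsets=onsets, fs=p.fs,
    )


def generate_cohort(params: GeneratorParams, waveforms=True):
    """Sample labels and (optionally) render every record.

    Returns a list of :class:`ECGRecord` when ``waveforms`` is true, else a
    list of ``(SubjectProfile, qt_ms, rr_sequence)`` label triples.  Each
    record's waveform noise uses an independent child seed so the cohort is
    reproducible record-by-record.
    """
    labels = sample_cohort(params)
    if not waveforms:
        return labels
    seeds = np.random.SeedSequence(params.seed).spawn(len(labels))
    records = []
    for lab, ss in zip(labels, seeds):
        records.append(synthesize_ecg(lab, params,
                                      rng=np.random.default_rng(ss)))
    return records


def noisy_oracle_predict(true_qtc_ms, params: NoisyOracleParams):
    """Surrogate regressor: truth + bias + slope*(truth - center) + noise."""
    truth = np.asarray(true_qtc_ms, dtype=float)
    rng = np.random.default_rng(params.seed)
    noise = rng.normal(0.0, params.noise_sd_ms, size=truth.shape) \
        if params.noise_sd_ms > 0 else 0.0
    return truth + params.bias_ms + params.slope * (truth - params.center_ms) \
        + noise


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def labels_frame(records):
    """Labels/demographics of a cohort as a DataFrame."""
    import pandas as pd

    rows = []
    for rec in records:
        if isinstance(rec, ECGRecord):
            prof, qt, rr, qtc = (rec.subject, rec.true_qt_ms,
                                 rec.true_mean_rr_ms, rec.true_qtc_ms)
        else:
            prof, qt, rr_seq = rec
            rr = float(np.mean(rr_seq))
            qtc = bazett_qtc(qt, rr)
        rows.append({
            "patient_id": prof.patient_id, "age_years": prof.age_years,
            "age_bin": prof.age_bin, "sex": prof.sex, "race": prof.race,
            "true_qt_ms": qt, "true_mean_rr_ms": rr, "true_qtc_ms": qtc,
        })
    return pd.DataFrame(rows)


def save_records_hdf5(path, records):
    """Persist a cohort (waveforms + labels) to one HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["leads"] = ",".join(LEADS)
        wf = np.stack([r.waveform for r in records]).astype(np.float32)
        f.create_dataset("waveforms", data=wf, compression="gzip")
        f.create_dataset("fs", data=records[0].fs)
        lab = labels_frame(records)
        for col in lab.columns:
            data = lab[col].to_numpy()
            if data.dtype == object:
                data = data.astype("S")
            f.create_dataset(f"labels/{col}", data=data)
        onsets = f.create_group("beat_onsets")
        for i, r in enumerate(records):
            onsets.create_dataset(str(i), data=r.beat_onsets)


def load_records_hdf5(path):
    import h5py

    records = []
    with h5py.File(path, "r") as f:
        wf = f["waveforms"][...]
        fs = float(f["fs"][()])
        lab = {k: f[f"labels/{k}"][...] for k in f["labels"]}
        for i in range(wf.shape[0]):
            prof = SubjectProfile(
                patient_id=lab["patient_id"][i].decode(),
                age_years=float(lab["age_years"][i]),
                sex=lab["sex"][i].decode(), race=lab["race"][i].decode(),
            )
            records.append(ECGRecord(
                waveform=wf[i].astype(np.float64), subject=prof,
                true_qt_ms=float(lab["true_qt_ms"][i]),
                true_mean_rr_ms=float(lab["true_mean_rr_ms"][i]),
                true_qtc_ms=float(lab["true_qtc_ms"][i]),
                beat_onsets=f[f"beat_onsets/{i}"][...], fs=fs,
            ))
    return records
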