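"""Synthetic SEEG-like recordings with a planted epileptogenic zone.

The generator emulates the connectivity structure the analysis targets, not
biophysically realistic waveforms.  Each unipolar contact carries

* pink (1/f) background noise, private to the contact;
* per high-frequency band (80-140, 140-200 Hz), a band-limited Gaussian
  source shared within its group (EZ shaft vs the rest) plus a global source
  shared by everyone, each received with a small per-contact lag (a few ms)
  so that lagged coherence and PLI — not zero-lag metrics — see the coupling;
* a low-frequency (3-8 Hz) ictal-discharge source during the seizure with
  distance-like per-contact propagation delays and phase-locking that ramps
  up toward termination.

Coupling weights follow a piecewise schedule on the normalized seizure axis
(onset 0, termination 1): the EZ's cross-group high-frequency weight drops in
mid-seizure (0.2-0.6 L), every weight is boosted post-ictally (1-1.2 L), and
the EZ's low-frequency weight is suppressed in early seizure (0-0.2 L).
Everything is deterministic given the seed.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .recording import ChannelInfo, Recording, SeizureAnnotation

__all__ = [
    "ScheduleSegment",
    "SimConfig",
    "GroundTruth",
    "SimulatedSeizure",
    "simulate_recording",
    "simulate_cohort",
    "DEFAULT_SCHEDULE",
]


@dataclass(frozen=True)
class ScheduleSegment:
    """Multiplier applied to a coupling weight on [t_lo, t_hi) of normalized time.

    ``target`` is ``"ez-cross"`` (EZ contacts' shared-global high-frequency
    weight), ``"all-hf"`` (every high-frequency weight), or ``"ez-lf"``
    (EZ contacts' low-frequency discharge weight).
    """

    t_lo: float
    t_hi: float
    target: str
    multiplier: float


DEFAULT_SCHEDULE = (
    ScheduleSegment(0.2, 0.6, "ez-cross", 0.25),  # mid-seizure EZ desynchronization
    ScheduleSegment(1.0, 1.2, "all-hf", 1.8),     # post-ictal widespread synchrony
    ScheduleSegment(1.0, 1.2, "ez-cross", 2.5),   # EZ resynchronizes post-ictally
    ScheduleSegment(0.0, 0.2, "ez-lf", 0.3),      # early-seizure EZ LF suppression
)

_VALID_TARGETS = {"ez-cross", "all-hf", "ez-lf"}


@dataclass
class SimConfig:
    """Study conditions for one synthetic seizure recording."""

    n_shafts: int = 5
    contacts_per_shaft: int = 5
    fs: float = 500.0
    preictal_s: float = 40.0
    seizure_s: float = 30.0
    postictal_s: float = 12.0
    ez_shafts: tuple[int, ...] = (0,)  # shaft indices forming the EZ
    rnez_contacts: int = 3  # leading contacts of the next shaft also resected
    hf_bands: tuple = ((80.0, 140.0), (140.0, 200.0))
    hf_amp: float = 1.0
    hf_private: float = 1.0  # per-contact in-band noise (sets coherence headroom)
    group_weight: float = 1.0
    cross_weight: float = 0.8
    lf_band: tuple[float, float] = (3.0, 8.0)
    lf_amp: float = 2.0
    lf_base_weight: float = 0.3
    lf_seizure_weight: float = 1.0
    lf_ramp_gain: float = 2.0  # weight multiplier reached at termination
    noise_sd: float = 1.0
    schedule: tuple[ScheduleSegment, ...] = DEFAULT_SCHEDULE
    seed: int = 0

    def __post_init__(self) -> None:
        for seg in self.schedule:
            if seg.target not in _VALID_TARGETS:
                raise ValueError(f"unknown schedule target {seg.target!r}")
        if not set(self.ez_shafts) <= set(range(self.n_shafts)):
            raise ValueError("ez_shafts outside shaft range")

    @property
    def duration_s(self) -> float:
        return self.preictal_s + self.seizure_s + self.postictal_s


@dataclass
class GroundTruth:
    """Planted structure of one simulated seizure."""

    ez_bipolar: list[str]
    resected_bipolar: list[str]
    schedule: tuple[ScheduleSegment, ...]
    state_boundaries: list[float]  # normalized times where the schedule switches
    onset_s: float
    termination_s: float

    def categories(self, labels: list[str]) -> list[str]:
        out = []
        for lab in labels:
            if lab in self.ez_bipolar:
                out.append("EZ")
            elif lab in self.resected_bipolar:
                out.append("RnEZ")
            else:
                out.append("nR")
        return out


@dataclass
class SimulatedSeizure:
    recording: Recording
    truth: GroundTruth
    patient_id: str = "p01"
    seizure_id: str = "sz1"
    age: float | None = None
    epilepsy_duration: float | None = None


def _bandlimited_noise(rng, n, fs, band, taps=None):
    x = rng.standard_normal(n)
    if taps is None:
        taps = signal.firwin(301, band, pass_zero=False, fs=fs)
    y = signal.oaconvolve(x, taps, mode="same")
    return y / y.std()


def _pink_noise(rng, n):
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    x = np.fft.irfft(spec / np.sqrt(f), n=n)
    return x / x.std()


def _segment_multiplier(t_norm, segments):
    mult = np.ones_like(t_norm)
    for seg in segments:
        mask = (t_norm >= seg.t_lo) & (t_norm < seg.t_hi)
        mult[mask] *= seg.multiplier
    return mult


def simulate_recording(cfg: SimConfig) -> tuple[Recording, GroundTruth]:
    """Generate one recording with its planted ground truth."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration_s * fs))
    onset_s = cfg.preictal_s
    term_s = cfg.preictal_s + cfg.seizure_s
    L = cfg.seizure_s
    t = np.arange(n) / fs
    t_norm = (t - onset_s) / L

    shaft_names = list(string.ascii_uppercase[: cfg.n_shafts])
    contacts = [
        (si, ci)
        for si in range(cfg.n_shafts)
        for ci in range(cfg.contacts_per_shaft)
    ]

    # shared sources per band: one per group (EZ / rest) plus one global
    hf_taps = {b: signal.firwin(301, b, pass_zero=False, fs=fs) for b in cfg.hf_bands}
    sources = {}
    for b in cfg.hf_bands:
        sources[b] = {
            "ez": _bandlimited_noise(rng, n, fs, b, hf_taps[b]),
            "rest": _bandlimited_noise(rng, n, fs, b, hf_taps[b]),
            "global": _bandlimited_noise(rng, n, fs, b, hf_taps[b]),
        }
    lf_source = _bandlimited_noise(rng, n, fs, cfg.lf_band)

    ez_cross_mult = _segment_multiplier(
        t_norm, [s for s in cfg.schedule if s.target == "ez-cross"]
    )
    all_hf_mult = _segment_multiplier(
        t_norm, [s for s in cfg.schedule if s.target == "all-hf"]
    )
    ez_lf_mult = _segment_multiplier(
        t_norm, [s for s in cfg.schedule if s.target == "ez-lf"]
    )

    # low-frequency discharge weight: baseline outside the seizure, full level
    # inside, linearly ramping toward termination (locking/amplitude rise)
    in_seizure = (t_norm >= 0) & (t_norm < 1)
    lf_weight = np.full(n, cfg.lf_base_weight)
    ramp = np.ones(n)
    ramp_zone = (t_norm >= 0.6) & (t_norm < 1.0)
    ramp[ramp_zone] = 1.0 + (cfg.lf_ramp_gain - 1.0) * (t_norm[ramp_zone] - 0.6) / 0.4
    lf_weight[in_seizure] = cfg.lf_seizure_weight * ramp[in_seizure]

    data = np.empty((len(contacts), n))
    chans = []
    for row, (si, ci) in enumerate(contacts):
        is_ez = si in cfg.ez_shafts
        group = "ez" if is_ez else "rest"
        # small per-contact lag so coupling is non-instantaneous; uniform
        # 2 ms increments keep every bipolar pair's retained source amplitude
        # statistically identical (unequal inter-contact lags would make the
        # planted contrast heterogeneous across pairs of the same shaft)
        hf_delay = int(round((2.0 * ci) / 1000.0 * fs))
        # traveling-discharge delays: ~15 ms between neighbouring contacts so
        # the phase lag survives bipolar subtraction at 4-8 Hz
        lf_delay = int(round((15.0 * ci + 10.0 * si) / 1000.0 * fs))
        x = cfg.noise_sd * _pink_noise(rng, n)
        for b in cfg.hf_bands:
            wg = cfg.group_weight * all_hf_mult
            wx = cfg.cross_weight * all_hf_mult
            if is_ez:
                wx = wx * ez_cross_mult
            x = x + cfg.hf_amp * (
                np.sqrt(wg) * np.roll(sources[b][group], hf_delay)
                + np.sqrt(wx) * np.roll(sources[b]["global"], hf_delay)
                + cfg.hf_private * _bandlimited_noise(rng, n, fs, b, hf_taps[b])
            )
        w_lf = lf_weight * (ez_lf_mult if is_ez else 1.0)
        x = x + cfg.lf_amp * w_lf * np.roll(lf_source, lf_delay)
        data[row] = x
        resected = is_ez or (
            si == min(set(range(cfg.n_shafts)) - set(cfg.ez_shafts), default=si)
            and ci < cfg.rnez_contacts
        )
        chans.append(
            ChannelInfo(
                label=f"{shaft_names[si]}{ci + 1}",
                shaft=shaft_names[si],
                contact_index=ci,
                gray_matter=True,
                resected=resected,
            )
        )

    ann = SeizureAnnotation(int(round(onset_s * fs)), int(round(term_s * fs)))
    rec = Recording(data, fs, chans, [ann])

    ez_bip, res_bip = [], []
    for si in range(cfg.n_shafts):
        name = shaft_names[si]
        for ci in range(cfg.contacts_per_shaft - 1):
            lab = f"{name}{ci + 1}-{name}{ci + 2}"
            a = chans[si * cfg.contacts_per_shaft + ci]
            b = chans[si * cfg.contacts_per_shaft + ci + 1]
            if a.resected and b.resected:
                res_bip.append(lab)
                if si in cfg.ez_shafts:
                    ez_bip.append(lab)
    boundaries = sorted({s.t_lo for s in cfg.schedule} | {s.t_hi for s in cfg.schedule})
    truth = GroundTruth(ez_bip, res_bip, cfg.schedule, boundaries, onset_s, term_s)
    return rec, truth


def simulate_cohort(
    n_patients: int = 13,
    seizures_per_patient: int = 3,
    template: SimConfig | None = None,
    seed: int = 0,
    schedule_families: int = 1,
) -> list[SimulatedSeizure]:
    """Cohort of patients with per-patient jitter of seizure length/contrast.

    Defaults give 13 x 3 = 39 seizures, the inventory scale of the regional
    statistics.  With ``schedule_families=2`` half of each patient's seizures
    use a shifted mid-seizure desynchronization window, emulating distinct
    epileptogenic network configurations (distinct state sequences).
    """
    template = template or SimConfig()
    root = np.random.default_rng(seed)
    cohort = []
    def _is_desync(seg: ScheduleSegment) -> bool:
        # the mid-seizure EZ decoupling segment, as opposed to the post-ictal
        # ez-cross boost
        return seg.target == "ez-cross" and seg.multiplier < 1.0

    alt_schedule = tuple(
        replace(s, t_lo=0.5, t_hi=0.9) if _is_desync(s) else s
        for s in template.schedule
    )
    for p in range(n_patients):
        prng = np.random.default_rng(root.integers(2**31 - 1))
        age = float(prng.uniform(18, 60))
        dur = float(prng.uniform(1, 30))
        for s in range(seizures_per_patient):
            sz_len = template.seizure_s * float(prng.uniform(0.8, 1.2))
            contrast = 0.25 * float(prng.uniform(0.8, 1.2))
            schedule = template.schedule
            if schedule_families == 2 and s % 2 == 1:
                schedule = alt_schedule
            schedule = tuple(
                replace(seg, multiplier=contrast) if _is_desync(seg) else seg
                for seg in schedule
            )
            cfg = replace(
                template,
                seizure_s=sz_len,
                schedule=schedule,
                seed=int(prng.integers(2**31 - 1)),
            )
            rec, truth = simulate_recording(cfg)
            cohort.append(
                SimulatedSeizure(
                    rec, truth, f"p{p + 1:02d}", f"sz{s + 1}", age, dur
                )
            )
    return cohort
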