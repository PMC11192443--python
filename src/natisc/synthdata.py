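"""Synthetic inputs for the ISC pipeline.

Everything the pipeline consumes can be generated here with fixed
seeds: region-level BOLD time courses with known stimulus-tracking
strength, resting-state scans, localizer t-map volumes, and free-text
description corpora for content-unit scoring.

The BOLD model is additive Gaussian with equal variance across
participants:

    x_i = sqrt(a) * s + sqrt(1 - a) * eps_i

where ``s`` is one shared stimulus-locked signal per condition and
``eps_i`` is participant-specific noise; both are temporally smoothed
Gaussian noise (default 3-TR FWHM, mimicking hemodynamic
autocorrelation) standardized to unit variance.  Under this model the
expected leave-one-out ISC has the closed form

    E[r] = a / sqrt(a + (1 - a) / (n - 1)),

which makes the generator self-calibrating: the default tracking
strengths a = {+M/+L: 0.11, +M/-L: 0.047, -M/-L: 0.003} put the mean
simulated ISC near 0.295 / 0.164 / 0.016 at n ~ 30.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ._rng import stream_rng
from .isc import TimeCourseSet
from .localizer import VoxelContrastMap

__all__ = [
    "ConditionSpec",
    "SimDesign",
    "DescriptionCorpus",
    "make_design",
    "expected_loo_isc",
    "simulate_timecourses",
    "simulate_rest",
    "simulate_peaked_timecourses",
    "simulate_tmap",
    "simulate_descriptions",
    "simulate_corpus",
    "DEFAULT_TRACKING",
    "DEFAULT_FROIS",
    "CONDITION_TYPES",
]

CONDITION_TYPES = ("+M/-L", "+M/+L", "-M/-L")
DEFAULT_FROIS = ("IFGorb", "IFG", "MFG", "AntTemp", "PostTemp")

# Tracking strengths solved from E[r] = a / sqrt(a + (1-a)/(n-1)) so the
# simulated condition-type means land near the calibration targets
# (0.295, 0.164, 0.016) at n ~ 30.
DEFAULT_TRACKING = {"+M/+L": 0.11, "+M/-L": 0.047, "-M/-L": 0.003}

# (name, type, duration in s incl. 2 x 16 s fixation, modality, N)
_PAPER_CONDITIONS = [
    ("AnimShort", "+M/-L", 5 * 60 + 48, "visual", 33),
    ("SilentFilm", "+M/-L", 6 * 60 + 10, "visual", 32),
    ("IntentShapes", "+M/-L", 4 * 60 + 50, "visual", 32),
    ("SoundEffectStory", "+M/-L", 4 * 60 + 36, "auditory", 31),
    ("Story", "+M/+L", 5 * 60 + 16, "auditory", 34),
    ("AudioPlay", "+M/+L", 6 * 60 + 14, "auditory", 31),
    ("Dialog", "+M/+L", 5 * 60 + 35, "auditory", 29),
    ("ExpoText", "+M/+L", 7 * 60 + 6, "auditory", 29),
    ("Flute", "-M/-L", 5 * 60 + 44, "auditory", 14),
    ("Kaleidoscope", "-M/-L", 5 * 60 + 48, "visual", 15),
]


@dataclass(frozen=True)
class ConditionSpec:
    """One naturalistic stimulus condition."""

    name: str
    condition_type: str
    duration_s: float
    modality: str
    n_participants: int
    fixation_s: float = 32.0  # 16 s pre + 16 s post, included in duration_s

    def __post_init__(self):
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.condition_type not in CONDITION_TYPES:
            raise ValueError(f"unknown condition type {self.condition_type!r}")
        if self.n_participants < 2:
            raise ValueError("ISC needs at least 2 participants per condition")
        if self.modality not in ("visual", "auditory"):
            raise ValueError(f"unknown modality {self.modality!r}")

    def n_samples(self, tr_s: float) -> int:
        return int(round((self.duration_s - self.fixation_s) / tr_s))


@dataclass
class SimDesign:
    """Full specification of one simulated experiment."""

    conditions: list
    tracking_strength: dict = field(default_factory=lambda: dict(DEFAULT_TRACKING))
    froi_modifiers: dict = field(default_factory=dict)
    frois: tuple = DEFAULT_FROIS
    tr_s: float = 2.0
    participation: dict = field(default_factory=dict)  # condition -> tuple of participants
    smoothing_fwhm_tr: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for level, a in self.tracking_strength.items():
            if not (0 <= a < 1):
                raise ValueError(f"tracking strength for {level!r} out of [0, 1): {a}")
        for cond in self.conditions:
            ps = self.participation.get(cond.name, ())
            if len(ps) < 2:
                raise ValueError(f"condition {cond.name!r} has fewer than 2 participants")
            for f in self.frois:
                if not (0 <= self.effective_a(cond.condition_type, f) < 1):
                    raise ValueError(
                        f"froi modifier for {f!r} pushes tracking strength outside [0, 1)"
                    )

    def effective_a(self, condition_type: str, froi: str) -> float:
        return self.tracking_strength[condition_type] * self.froi_modifiers.get(froi, 1.0)

    def condition(self, name: str) -> ConditionSpec:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def condition_types(self) -> dict:
        return {c.name: c.condition_type for c in self.conditions}

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "conditions": [vars(c) for c in self.conditions],
            "tracking_strength": dict(self.tracking_strength),
            "froi_modifiers": dict(self.froi_modifiers),
            "frois": list(self.frois),
            "tr_s": self.tr_s,
            "participation": {k: list(v) for k, v in self.participation.items()},
            "smoothing_fwhm_tr": self.smoothing_fwhm_tr,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimDesign":
        d = dict(d)
        d["conditions"] = [ConditionSpec(**c) for c in d["conditions"]]
        d["frois"] = tuple(d["frois"])
        d["participation"] = {k: tuple(v) for k, v in d["participation"].items()}
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SimDesign":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def make_design(template: str = "paper", seed: int = 0) -> SimDesign:
    """Build a SimDesign from a named template.

    ``"paper"`` reproduces the study layout: 10 conditions with the
    published Ns {33,32,32,31,34,31,29,29,14,15} and durations, five
    language fROIs, and a 47-participant pool assigned to conditions at
    random (seeded) to match the per-condition Ns.  ``"small"`` is a
    3-condition miniature (one condition per type, 10-participant pool,
    2 fROIs) for smoke tests.
    """
    if template == "paper":
        conds = [ConditionSpec(*row) for row in _PAPER_CONDITIONS]
        pool = [f"P{i:02d}" for i in range(1, 48)]
        frois = DEFAULT_FROIS
    elif template == "small":
        conds = [
            ConditionSpec("MiniFilm", "+M/-L", 152.0, "visual", 8),
            ConditionSpec("MiniStory", "+M/+L", 152.0, "auditory", 8),
            ConditionSpec("MiniMusic", "-M/-L", 152.0, "auditory", 8),
        ]
        pool = [f"P{i:02d}" for i in range(1, 11)]
        frois = ("AntTemp", "PostTemp")
    else:
        raise ValueError(f"unknown design template {template!r}")

    rng = stream_rng(seed, "participation")
    participation = {
        c.name: tuple(sorted(rng.choice(pool, size=c.n_participants, replace=False)))
        for c in conds
    }
    return SimDesign(conditions=conds, frois=frois, participation=participation, seed=seed)


def expected_loo_isc(a: float, n: int) -> float:
    """Closed-form expected leave-one-out ISC under the additive model."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if a == 0:
        return 0.0
    return a / np.sqrt(a + (1 - a) / (n - 1))


def _smooth_unit(x: np.ndarray, fwhm_tr: float) -> np.ndarray:
    """Gaussian-smooth and standardize to mean 0, unit (n-1) variance."""
    if fwhm_tr > 0:
        x = gaussian_filter1d(x, sigma=fwhm_tr / 2.354820045, mode="nearest")
    return (x - x.mean()) / x.std(ddof=1)


def simulate_timecourses(design: SimDesign) -> TimeCourseSet:
    """Simulate region-level BOLD series for every participating cell.

    For each (participant, condition, fROI): ``x = sqrt(a)*s +
    sqrt(1-a)*eps`` with the shared signal ``s`` drawn once per
    condition (common to all fROIs) and ``eps`` drawn per participant
    and fROI; both streams are smoothed and standardized identically.
    Deterministic given ``design.seed``.
    """
    data = {}
    for cond in design.conditions:
        T = cond.n_samples(design.tr_s)
        sig_rng = stream_rng(design.seed, "signal", cond.name)
        s = _smooth_unit(sig_rng.standard_normal(T), design.smoothing_fwhm_tr)
        for p in design.participation[cond.name]:
            for f in design.frois:
                a = design.effective_a(cond.condition_type, f)
                noise_rng = stream_rng(design.seed, "noise", cond.name, p, f)
                eps = _smooth_unit(noise_rng.standard_normal(T), design.smoothing_fwhm_tr)
                data[(p, cond.name, f)] = np.sqrt(a) * s + np.sqrt(1 - a) * eps
    return TimeCourseSet(
        data=data, tr_s=design.tr_s, condition_types=design.condition_types()
    )


def simulate_rest(
    n_participants: int = 10,
    duration_s: float = 300.0,
    design: SimDesign | None = None,
    seed: int | None = None,
) -> TimeCourseSet:
    """Pure-noise resting-state series (tracking strength a = 0).

    No fixation padding and no onset structure: ``duration_s`` is scan
    time, so the default 300 s yields 150 samples at TR = 2 s.  The
    condition is labeled ``"rest"``.
    """
    if n_participants < 2:
        raise ValueError("rest ISC needs at least 2 participants (leave-one-out)")
    if design is None:
        design = make_design("paper", seed=0)
    if seed is None:
        seed = design.seed
    T = int(round(duration_s / design.tr_s))
    data = {}
    for i in range(1, n_participants + 1):
        p = f"R{i:02d}"
        for f in design.frois:
            rng = stream_rng(seed, "rest", p, f)
            data[(p, "rest", f)] = _smooth_unit(
                rng.standard_normal(T), design.smoothing_fwhm_tr
            )
    return TimeCourseSet(data=data, tr_s=design.tr_s, condition_types={"rest": "rest"})


def simulate_peaked_timecourses(
    n_participants: int = 20,
    n_timepoints: int = 200,
    n_frois: int = 3,
    burst_frac: float = 0.10,
    burst_amplitude: float = 3.0,
    seed: int = 0,
    condition: str = "BurstClip",
) -> tuple[TimeCourseSet, np.ndarray]:
    """Series whose shared signal is concentrated in high-excursion bursts.

    The shared component is (near) zero outside a random set of
    ``burst_frac * T`` time points and has amplitude ``burst_amplitude``
    inside it, so the group-average series exceeds z = 1 exactly at the
    bursts and the intersubject coupling lives entirely in those peaks.
    Returns the TimeCourseSet (condition type ``"+M/-L"``) and the
    sorted burst indices in raw (pre-trim) coordinates.
    """
    rng = stream_rng(seed, "burst-design")
    m = max(1, int(round(burst_frac * n_timepoints)))
    bursts = np.sort(rng.choice(n_timepoints, size=m, replace=False))
    s = np.zeros(n_timepoints)
    s[bursts] = burst_amplitude * (1.0 + 0.1 * rng.standard_normal(m))
    data = {}
    for i in range(1, n_participants + 1):
        p = f"B{i:02d}"
        for j in range(n_frois):
            f = f"froi{j+1}"
            noise = stream_rng(seed, "burst-noise", p, f).standard_normal(n_timepoints)
            data[(p, condition, f)] = s + noise
    tcs = TimeCourseSet(
        data=data, tr_s=2.0, onset_exclusion_s=0.0, condition_types={condition: "+M/-L"}
    )
    return tcs, bursts


def simulate_tmap(
    parcel_shape: tuple,
    n_signal_voxels: int,
    signal_t: float,
    noise_sd: float,
    seed: int = 0,
    df: int = 100,
    block_start: int = 0,
    gm_exclude_frac: float = 0.0,
    parcel_name: str = "parcel",
) -> VoxelContrastMap:
    """Localizer-contrast t-map fixture with a planted contiguous block.

    A block of ``n_signal_voxels`` consecutive voxels (linear order,
    starting at ``block_start``) has mean ``signal_t``; the background
    has mean 0; Gaussian noise with ``noise_sd`` is added everywhere.
    ``gm_exclude_frac`` of the non-signal voxels are marked non-GM.
    """
    n_total = int(np.prod(parcel_shape))
    if n_signal_voxels > n_total:
        raise ValueError("n_signal_voxels exceeds the parcel size")
    if block_start + n_signal_voxels > n_total:
        raise ValueError("signal block does not fit in the parcel")
    rng = stream_rng(seed, "tmap")
    t = noise_sd * rng.standard_normal(n_total)
    block = np.arange(block_start, block_start + n_signal_voxels)
    t[block] += signal_t
    gm = np.ones(n_total, dtype=bool)
    if gm_exclude_frac > 0:
        bg = np.setdiff1d(np.arange(n_total), block)
        n_out = int(round(gm_exclude_frac * len(bg)))
        gm[rng.choice(bg, size=n_out, replace=False)] = False
    parcel = np.ones(n_total, dtype=bool)
    return VoxelContrastMap(
        t_values=t,
        df=df,
        gm_mask=gm,
        parcel_masks={parcel_name: parcel},
        shape=tuple(parcel_shape),
    )


# ---------------------------------------------------------------------
# Description corpora
# ---------------------------------------------------------------------

@dataclass
class DescriptionCorpus:
    """Free-text descriptions keyed (stimulus, subclip index, participant)."""

    texts: dict = field(default_factory=dict)  # stimulus -> {subclip -> {participant -> text}}
    n_selected: int = 20

    def stimuli(self) -> list:
        return sorted(self.texts)

    def subclips(self, stimulus: str) -> list:
        return sorted(self.texts[stimulus])

    def participants(self, stimulus: str) -> list:
        ps: set = set()
        for sub in self.texts[stimulus].values():
            ps.update(sub)
        return sorted(ps)

    def to_json(self, path) -> None:
        ser = {
            s: {str(k): dict(v) for k, v in subs.items()}
            for s, subs in self.texts.items()
        }
        with open(path, "w") as fh:
            json.dump({"n_selected": self.n_selected, "texts": ser}, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "DescriptionCorpus":
        with open(path) as fh:
            raw = json.load(fh)
        texts = {
            s: {int(k): dict(v) for k, v in subs.items()}
            for s, subs in raw["texts"].items()
        }
        return cls(texts=texts, n_selected=raw.get("n_selected", 20))


# Concept vocabulary: lemma -> inflected surface forms, chosen so the
# rule-based lemmatizer is genuinely exercised (plurals, -ing, -ed,
# irregulars).
_CONCEPT_VOCAB = [
    ("bird", ["bird", "birds"]),
    ("dog", ["dog", "dogs"]),
    ("cloud", ["cloud", "clouds"]),
    ("baby", ["baby", "babies"]),
    ("stork", ["stork", "storks"]),
    ("church", ["church", "churches"]),
    ("box", ["box", "boxes"]),
    ("man", ["man", "men"]),
    ("child", ["child", "children"]),
    ("foot", ["foot", "feet"]),
    ("run", ["run", "running", "ran"]),
    ("fly", ["fly", "flying", "flew"]),
    ("sit", ["sit", "sitting", "sat"]),
    ("chase", ["chase", "chasing", "chased"]),
    ("jump", ["jump", "jumping", "jumped"]),
    ("fall", ["fall", "falling", "fell"]),
    ("dance", ["dance", "dancing", "danced"]),
    ("sleep", ["sleep", "sleeping", "slept"]),
    ("eat", ["eat", "eating", "ate"]),
    ("throw", ["throw", "throwing", "threw"]),
    ("door", ["door", "doors"]),
    ("shape", ["shape", "shapes"]),
    ("circle", ["circle", "circles"]),
    ("triangle", ["triangle", "triangles"]),
    ("alarm", ["alarm", "alarms"]),
    ("kitchen", ["kitchen"]),
    ("tree", ["tree", "trees"]),
    ("flute", ["flute"]),
    ("pattern", ["pattern", "patterns"]),
    ("color", ["color", "colors"]),
]

_FILLER_PHRASES = [
    "I think", "I believe", "it seems like", "In this clip", "Same as before",
    "the camera", "it appears to be", "I guess", "seems like", "the screen",
]
_FILLER_GLUE = ["the", "a", "and", "then", "is", "was", "there"]


def simulate_descriptions(
    n_participants: int = 20,
    n_subclips: int = 10,
    core_concepts_per_subclip: int = 5,
    share_prob: float = 0.7,
    filler: bool = True,
    seed: int = 0,
    stimulus: str = "stim",
    vocab_size: int | None = None,
) -> DescriptionCorpus:
    """Generate per-participant subclip descriptions with known overlap.

    Each subclip is assigned ``core_concepts_per_subclip`` core concepts
    from a fixed vocabulary; each participant mentions each core concept
    independently with probability ``share_prob``, using a randomly
    chosen inflected surface form (so lemmatization is exercised).  With
    ``filler=True``, self-referential / meta / confidence phrases and
    stop words are interleaved; the filler stream is seeded separately
    from the concept stream, so toggling it never changes which concepts
    are mentioned.
    """
    if n_participants <= 0 or n_subclips <= 0 or core_concepts_per_subclip <= 0:
        raise ValueError("counts must be positive")
    if not (0 <= share_prob <= 1):
        raise ValueError("share_prob must be in [0, 1]")
    vocab = _CONCEPT_VOCAB[: (vocab_size or len(_CONCEPT_VOCAB))]
    concept_rng = stream_rng(seed, "concepts", stimulus)
    texts: dict = {}
    for clip in range(n_subclips):
        idx = concept_rng.choice(len(vocab), size=min(core_concepts_per_subclip, len(vocab)),
                                 replace=False)
        core = [vocab[i] for i in idx]
        texts[clip] = {}
        for j in range(1, n_participants + 1):
            p = f"S{j:02d}"
            mention_rng = stream_rng(seed, "mention", stimulus, clip, p)
            words = []
            for lemma, forms in core:
                if mention_rng.random() < share_prob:
                    words.append(forms[mention_rng.integers(len(forms))])
            if filler:
                filler_rng = stream_rng(seed, "filler", stimulus, clip, p)
                out = []
                for w in words:
                    if filler_rng.random() < 0.3:
                        out.append(str(filler_rng.choice(_FILLER_PHRASES)))
                    if filler_rng.random() < 0.5:
                        out.append(str(filler_rng.choice(_FILLER_GLUE)))
                    out.append(w)
                if filler_rng.random() < 0.5:
                    out.append(str(filler_rng.choice(_FILLER_PHRASES)))
                words = out
            texts[clip][p] = " ".join(words)
    return DescriptionCorpus(texts={stimulus: texts}, n_selected=n_participants)


def simulate_corpus(
    design: SimDesign,
    n_participants: int = 20,
    n_subclips: int = 10,
    concepts_by_type: dict | None = None,
    share_prob: float = 0.7,
    filler: bool = True,
    seed: int | None = None,
) -> DescriptionCorpus:
    """One description corpus per condition in ``design``.

    Meaningful (+M) stimuli get rich per-subclip concept sets and
    non-meaningful (-M) stimuli sparse ones, emulating the semantic
    richness difference the content-unit metric is meant to detect.
    """
    if concepts_by_type is None:
        concepts_by_type = {"+M/+L": 10, "+M/-L": 10, "-M/-L": 2}
    if seed is None:
        seed = design.seed
    texts = {}
    for cond in design.conditions:
        k = concepts_by_type[cond.condition_type]
        sub = simulate_descriptions(
            n_participants=n_participants,
            n_subclips=n_subclips,
            core_concepts_per_subclip=k,
            share_prob=share_prob,
            filler=filler,
            seed=seed,
            stimulus=cond.name,
        )
        texts[cond.name] = sub.texts[cond.name]
    return DescriptionCorpus(texts=texts, n_selected=n_participants)
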