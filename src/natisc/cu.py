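"""Content-Unit (CU) scoring of free-text stimulus descriptions.

A CU is a concept (object, entity, action, property, ...) referenced in
a verbal description of a stimulus, operationalized as a lemma string
after cleaning.  The chain: remove content-irrelevant phrases
(self-referential, meta-descriptive, confidence language), strip stop
words, lemmatize, merge multiword proper nouns, then (a) include only
lemmas used by >= 3 participants for the stimulus, (b) count tokens of
included lemmas per response (a word repeated within one subclip
response counts each time, because the same entity can participate in
multiple events), and (c) optionally count lemma types shared between
participant pairs as a description-similarity analogue of ISC.

Lemmatization is rule-based (regular plural / -ing / -ed stripping plus
an irregular-form table): adequate for the controlled synthetic corpora
this pipeline consumes and dependency-free.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import LMEFit, compare_models, fit_condition_model, fit_lme

__all__ = [
    "CUTable",
    "default_lexicons",
    "default_stopwords",
    "clean_description",
    "lemmatize_word",
    "extract_lemmas",
    "count_cus",
    "shared_cu_pairwise",
    "cu_condition_model",
    "cu_isc_association",
]

_VOWELS = set("aeiouy")

_IRREGULAR = {
    # verbs
    "was": "be", "were": "be", "is": "be", "are": "be", "am": "be", "been": "be", "being": "be",
    "has": "have", "had": "have", "did": "do", "done": "do",
    "sat": "sit", "ran": "run", "went": "go", "gone": "go", "saw": "see", "seen": "see",
    "made": "make", "flew": "fly", "flown": "fly", "got": "get", "gotten": "get",
    "took": "take", "taken": "take", "gave": "give", "given": "give", "came": "come",
    "stood": "stand", "fell": "fall", "fallen": "fall", "felt": "feel", "left": "leave",
    "said": "say", "told": "tell", "thought": "think", "knew": "know", "known": "know",
    "held": "hold", "kept": "keep", "sang": "sing", "sung": "sing", "ate": "eat",
    "eaten": "eat", "drank": "drink", "wore": "wear", "woke": "wake", "began": "begin",
    "begun": "begin", "broke": "break", "broken": "break", "brought": "bring",
    "bought": "buy", "caught": "catch", "chose": "choose", "chosen": "choose",
    "drew": "draw", "drawn": "draw", "drove": "drive", "driven": "drive",
    "found": "find", "heard": "hear", "hid": "hide", "lost": "lose", "met": "meet",
    "paid": "pay", "rode": "ride", "rose": "rise", "sold": "sell", "sent": "send",
    "showed": "show", "shown": "show", "slept": "sleep", "spoke": "speak",
    "swam": "swim", "threw": "throw", "thrown": "throw", "understood": "understand",
    "won": "win", "wrote": "write", "written": "write", "rang": "ring", "rung": "ring",
    # nouns
    "men": "man", "women": "woman", "children": "child", "people": "person",
    "mice": "mouse", "feet": "foot", "teeth": "tooth", "geese": "goose",
}

_DOUBLES_KEEP = {"ll", "ss", "zz", "ff"}


def _read_lexicon(name: str) -> list[str]:
    text = resources.files("natisc").joinpath(f"data/{name}.txt").read_text("utf8")
    return [line.strip() for line in text.splitlines() if line.strip()]


def default_lexicons() -> dict:
    """The shipped filler-phrase lexicons (self_ref, meta, confidence)."""
    return {
        "self_ref": _read_lexicon("selfref"),
        "meta": _read_lexicon("meta"),
        "confidence": _read_lexicon("confidence"),
    }


def default_stopwords() -> frozenset:
    return frozenset(_read_lexicon("stopwords"))


def clean_description(text: str, lexicons: dict | None = None) -> str:
    """Remove content-irrelevant phrases, case-insensitively.

    Matched phrases (longest first, at word boundaries) are deleted and
    the remainder is whitespace-normalized.  An empty result is allowed.
    """
    if lexicons is None:
        lexicons = default_lexicons()
    phrases = sorted(
        {p for plist in lexicons.values() for p in plist}, key=len, reverse=True
    )
    out = text
    for phrase in phrases:
        pattern = re.compile(r"\b" + re.escape(phrase) + r"\b", flags=re.IGNORECASE)
        out = pattern.sub(" ", out)
    return re.sub(r"\s+", " ", out).strip()


def lemmatize_word(word: str) -> str:
    """Map one lowercase word to its lemma by rule.

    Irregular table first, then suffix rules: -ies -> -y, plural -s/-es,
    -ing and -ed with consonant un-doubling (sitting -> sit) and final-e
    restoration for C-V-C stems (chasing -> chase).
    """
    w = word
    if w in _IRREGULAR:
        return _IRREGULAR[w]

    def _restore(stem: str) -> str:
        if len(stem) >= 2 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS \
                and stem[-2:] not in _DOUBLES_KEEP:
            return stem[:-1]
        if (
            len(stem) >= 3
            and stem[-1] not in _VOWELS
            and stem[-1] not in "wx"
            and stem[-2] in _VOWELS
            and stem[-2] != "y"
            and stem[-3] not in _VOWELS
        ):
            return stem + "e"
        if len(stem) >= 3 and stem[-1] in "cgv" and stem[-2] not in _VOWELS:
            return stem + "e"  # danc -> dance, chang -> change
        return stem

    if w.endswith("ing") and len(w) > 5:
        return _restore(w[:-3])
    if w.endswith("ied") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("ed") and len(w) > 4:
        return _restore(w[:-2])
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith("sses"):
        return w[:-2]
    if w.endswith("es") and len(w) > 3 and w[-3] in "sxz":
        return w[:-2]
    if w.endswith(("ches", "shes")):
        return w[:-2]
    if w.endswith("s") and len(w) > 3 and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


def extract_lemmas(
    text: str,
    stopwords: frozenset | None = None,
    proper_noun_merges=(),
) -> list[str]:
    """Tokenize, merge proper nouns, drop stop words, lemmatize.

    Multiword proper nouns (e.g. "Mr. Bean") become single tokens with
    spaces replaced by underscores, keeping their capitalization; all
    other tokens are lowercased and lemmatized.  Returns the ordered
    lemma list.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    placeholders = {}
    for i, name in enumerate(proper_noun_merges):
        token = name.replace(" ", "_")
        key = "xpropnoun" + "".join(chr(97 + int(c)) for c in str(i)) + "x"
        pattern = re.compile(re.escape(name), flags=re.IGNORECASE)
        text, n = pattern.subn(f" {key} ", text)
        if n:
            placeholders[key] = token
    words = re.findall(r"[A-Za-z][A-Za-z']*", text)
    out = []
    for w in words:
        lw = w.lower()
        if lw in placeholders:
            out.append(placeholders[lw])
            continue
        lw = lw.strip("'")
        if not lw or lw in stopwords:
            continue
        out.append(lemmatize_word(lw))
    return out


@dataclass
class CUTable:
    """Per-(stimulus, subclip, participant) CU counts and shared-pair summaries."""

    counts: pd.DataFrame  # stimulus, subclip, participant, cu_count
    included_lexicon: dict = field(default_factory=dict)  # stimulus -> frozenset of lemmas
    shared_pairwise: pd.DataFrame | None = None  # stimulus, subclip, shared_mean

    def mean_cu_per_stimulus(self) -> pd.Series:
        """Mean over subclips of the participant-averaged subclip count."""
        per_sub = self.counts.groupby(["stimulus", "subclip"])["cu_count"].mean()
        return per_sub.groupby("stimulus").mean()

    def mean_shared_per_stimulus(self) -> pd.Series:
        if self.shared_pairwise is None:
            raise ValueError("shared_pairwise not computed")
        return self.shared_pairwise.groupby("stimulus")["shared_mean"].mean()


def _lemma_cells(corpus, stimulus, stopwords, lexicons, proper_noun_merges) -> dict:
    """(subclip, participant) -> lemma token list, after the full cleaning chain."""
    cells = {}
    for subclip, by_p in corpus.texts[stimulus].items():
        for participant, text in by_p.items():
            cleaned = clean_description(text, lexicons)
            cells[(subclip, participant)] = extract_lemmas(
                cleaned, stopwords=stopwords, proper_noun_merges=proper_noun_merges
            )
    return cells


def _included_lexicon(cells: dict, min_participants: int) -> frozenset:
    users: dict = {}
    for (subclip, participant), lemmas in cells.items():
        for lem in set(lemmas):
            users.setdefault(lem, set()).add(participant)
    return frozenset(l for l, ps in users.items() if len(ps) >= min_participants)


def count_cus(
    corpus,
    stimulus: str,
    min_participants: int = 3,
    stopwords: frozenset | None = None,
    lexicons: dict | None = None,
    proper_noun_merges=(),
) -> CUTable:
    """CU counts for one stimulus.

    The inclusion lexicon is the set of lemmas used by at least
    ``min_participants`` distinct participants anywhere in the stimulus;
    each (participant, subclip) count is the number of TOKENS of
    included lemmas in that response (repeats count).  Pairwise shared
    types per subclip are filled in by :func:`shared_cu_pairwise`.
    """
    if stopwords is None:
        stopwords = default_stopwords()
    cells = _lemma_cells(corpus, stimulus, stopwords, lexicons, proper_noun_merges)
    lexicon = _included_lexicon(cells, min_participants)
    rows = [
        {
            "stimulus": stimulus,
            "subclip": subclip,
            "participant": participant,
            "cu_count": sum(1 for lem in lemmas if lem in lexicon),
        }
        for (subclip, participant), lemmas in sorted(cells.items())
    ]
    return CUTable(counts=pd.DataFrame(rows), included_lexicon={stimulus: lexicon})


def shared_cu_pairwise(
    corpus,
    stimulus: str,
    min_participants: int = 3,
    stopwords: frozenset | None = None,
    lexicons: dict | None = None,
    proper_noun_merges=(),
) -> pd.DataFrame:
    """Mean pairwise shared CU types per subclip.

    For each subclip and each unordered participant pair, the number of
    included-lemma TYPES present in both responses; averaged over pairs.
    Returns a DataFrame (stimulus, subclip, shared_mean).
    """
    if stopwords is None:
        stopwords = default_stopwords()
    cells = _lemma_cells(corpus, stimulus, stopwords, lexicons, proper_noun_merges)
    lexicon = _included_lexicon(cells, min_participants)
    subclips = sorted({s for (s, _) in cells})
    rows = []
    for subclip in subclips:
        typesets = {
            p: frozenset(l for l in lemmas if l in lexicon)
            for (s, p), lemmas in cells.items()
            if s == subclip
        }
        ps = sorted(typesets)
        if len(ps) < 2:
            raise ValueError(f"subclip {subclip!r} has fewer than 2 participants")
        shared = [
            len(typesets[a] & typesets[b]) for a, b in itertools.combinations(ps, 2)
        ]
        rows.append({"stimulus": stimulus, "subclip": subclip, "shared_mean": float(np.mean(shared))})
    return pd.DataFrame(rows)


def score_corpus(corpus, min_participants: int = 3, **kw) -> CUTable:
    """Run count_cus + shared_cu_pairwise over every stimulus in a corpus."""
    counts, shared, lexica = [], [], {}
    for stim in corpus.stimuli():
        tab = count_cus(corpus, stim, min_participants=min_participants, **kw)
        counts.append(tab.counts)
        lexica.update(tab.included_lexicon)
        shared.append(shared_cu_pairwise(corpus, stim, min_participants=min_participants, **kw))
    return CUTable(
        counts=pd.concat(counts, ignore_index=True),
        included_lexicon=lexica,
        shared_pairwise=pd.concat(shared, ignore_index=True),
    )


def cu_condition_model(cu: CUTable, condition_types: dict, reml: bool = True) -> LMEFit:
    """Model participant-averaged subclip CU counts by condition type.

    Response: per-(stimulus, subclip) mean CU count across participants;
    fixed effect: condition type (dummy coded, +M/-L reference); random
    intercept: stimulus.  A singular stimulus intercept is flagged, not
    hidden (expected with few stimuli per type).
    """
    per_sub = (
        cu.counts.groupby(["stimulus", "subclip"])["cu_count"].mean().reset_index()
    )
    per_sub["condition_type"] = per_sub["stimulus"].map(condition_types)
    if per_sub["condition_type"].isna().any():
        missing = per_sub.loc[per_sub["condition_type"].isna(), "stimulus"].unique()
        raise ValueError(f"no condition type for stimuli: {sorted(missing)}")
    if per_sub["condition_type"].nunique() < 2:
        raise ValueError("need at least 2 condition types")
    return fit_lme(
        per_sub,
        'C(condition_type, Treatment("+M/-L"))',
        vc_factors=["stimulus"],
        formula_id="cu_condition_type",
        reference_level="+M/-L",
        reml=reml,
        response="cu_count",
    )


def cu_isc_association(
    cu: CUTable,
    isc: pd.DataFrame,
    metric: str = "mean_cu",
    scope=None,
) -> dict:
    """Correlate stimulus-level CU values with stimulus-level ISCs.

    ``metric`` is ``"mean_cu"`` (participant-averaged counts) or
    ``"shared_cu"`` (mean pairwise shared types).  ``scope`` is the
    explicit stimulus subset for the Pearson correlation (required to be
    >= 3 stimuli; a constant CU metric is an error).  The three-model
    comparison — condition type only, + centered CU (likelihood-ratio
    test), CU only (AIC difference) — is fit on the full ISC table.
    Returns a dict with r, p, n_stimuli, and the model comparisons.
    """
    if metric == "mean_cu":
        cu_per_stim = cu.mean_cu_per_stimulus()
    elif metric == "shared_cu":
        cu_per_stim = cu.mean_shared_per_stimulus()
    else:
        raise ValueError(f"unknown metric {metric!r}")
    isc = isc[isc["condition_type"] != "rest"]
    isc_per_stim = isc.groupby("condition")["z"].mean()
    common = sorted(set(cu_per_stim.index) & set(isc_per_stim.index))
    if scope is None:
        scope = common
    scope = [s for s in scope if s in common]
    if len(scope) < 3:
        raise ValueError("correlation scope must contain at least 3 stimuli")
    x = cu_per_stim.loc[scope].to_numpy(dtype=float)
    y = isc_per_stim.loc[scope].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("CU metric is constant across the scope; correlation undefined")
    r, p = sps.pearsonr(x, y)

    # model comparisons on the full table, CU centered across stimuli
    data = isc[isc["condition"].isin(common)].copy()
    cu_centered = cu_per_stim.loc[common] - cu_per_stim.loc[common].mean()
    data["cu_c"] = data["condition"].map(cu_centered)
    original = fit_condition_model(data, reml=False)
    cu_only = fit_lme(
        data,
        "cu_c",
        vc_factors=["froi", "participant", "condition"],
        formula_id="cu_only",
        reference_level=None,
        reml=False,
    )
    aic = compare_models(original, cu_only, nested=False)
    out = {
        "metric": metric,
        "pearson_r": float(r),
        "p": float(p),
        "n_stimuli": len(scope),
        "delta_aic_cu_only": aic["delta_aic"],
        "fits": {"original": original, "cu_only": cu_only},
    }
    # With as many condition-type levels as stimuli, cu_c is collinear
    # with the type dummies and the joint model is unidentifiable.
    n_types = data["condition_type"].nunique()
    if len(common) <= n_types:
        out["lrt_add_cu"] = None
        out["cu_beta_in_joint_model"] = None
        out["joint_model_note"] = (
            "CU covariate is collinear with condition type "
            f"({len(common)} stimuli, {n_types} types); joint model skipped"
        )
        return out
    plus_cu = fit_lme(
        data,
        'C(condition_type, Treatment("+M/-L")) + cu_c',
        vc_factors=["froi", "participant", "condition"],
        formula_id="condition_type+cu",
        reference_level="+M/-L",
        reml=False,
    )
    out["lrt_add_cu"] = compare_models(original, plus_cu, nested=True)
    out["cu_beta_in_joint_model"] = plus_cu.coef("cu_c")
    out["fits"]["plus_cu"] = plus_cu
    return out
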