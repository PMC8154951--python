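"""Audiovisual statistical-learning stimulus design.

Builds the four CVCVCV nonsense words (two of them carrying a vowel- or
consonant-harmony cue), the familiarization stream in which transitional
probability (TP) is 1 between syllables within a word and 0.5 between
words and between images, and the counterbalanced two-alternative test
trial schedules.

The stream is an alternation of object-word events (a still picture of a
woman) and action-word events (a video of a head gesture performed by the
same woman as the preceding picture).  Exact TP balance is obtained by
constructing the stream as an Eulerian circuit on a transition multigraph,
so every allowed transition occurs equally often around the cycle.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Word",
    "ImageToken",
    "DesignConfig",
    "StreamSpec",
    "StreamEvent",
    "TestTrial",
    "TestTrialSchedule",
    "TransitionTable",
    "InventoryError",
    "DEFAULT_CONSONANTS",
    "DEFAULT_VOWELS",
    "make_words",
    "build_familiarization_sequence",
    "schedule_stream",
    "compute_transition_table",
    "build_test_trials",
    "counterbalance_versions",
]

DEFAULT_CONSONANTS = ("b", "d", "f", "g", "k", "l", "m", "n", "p", "r", "s", "t")
DEFAULT_VOWELS = ("a", "e", "i", "o", "u")


class InventoryError(ValueError):
    """Raised when the phoneme inventory cannot yield 12 distinct syllables."""


@dataclass(frozen=True)
class Word:
    """A trisyllabic CV.CV.CV nonsense word."""

    label: str
    syllables: tuple[str, str, str]
    harmony: str  # "vowel" | "consonant" | "none"
    word_role: str  # "object" | "action"

    def __post_init__(self) -> None:
        if len(self.syllables) != 3:
            raise ValueError("a word has exactly 3 syllables")
        for syl in self.syllables:
            if len(syl) != 2:
                raise ValueError(f"syllable {syl!r} is not CV")
        if self.harmony == "vowel" and len({s[1] for s in self.syllables}) != 1:
            raise ValueError("vowel harmony requires one vowel across syllables")
        if self.harmony == "consonant" and len({s[0] for s in self.syllables}) != 1:
            raise ValueError("consonant harmony requires one consonant")
        if self.harmony not in ("vowel", "consonant", "none"):
            raise ValueError(f"unknown harmony {self.harmony!r}")
        if self.word_role not in ("object", "action"):
            raise ValueError(f"unknown role {self.word_role!r}")

    @property
    def phonemes(self) -> tuple[tuple[str, str], ...]:
        """Ordered (symbol, class) pairs, class in {'consonant', 'vowel'}."""
        out: list[tuple[str, str]] = []
        for syl in self.syllables:
            out.append((syl[0], "consonant"))
            out.append((syl[1], "vowel"))
        return tuple(out)


@dataclass(frozen=True)
class ImageToken:
    """One of the six visual stimuli: 2 pictures and 4 head-gesture videos."""

    kind: str  # "picture" | "video"
    woman: str  # "A" | "B"
    gesture: str = "none"  # "none" | "up_down" | "left_right"

    def __post_init__(self) -> None:
        if self.kind not in ("picture", "video"):
            raise ValueError(f"unknown kind {self.kind!r}")
        if self.woman not in ("A", "B"):
            raise ValueError(f"unknown woman {self.woman!r}")
        if (self.gesture == "none") != (self.kind == "picture"):
            raise ValueError("gesture is 'none' iff the token is a picture")

    def as_str(self) -> str:
        return f"{self.kind}:{self.woman}:{self.gesture}"


def make_words(
    harmony_type: str,
    role_of_cued: str,
    consonants: Sequence[str] = DEFAULT_CONSONANTS,
    vowels: Sequence[str] = DEFAULT_VOWELS,
    rng_seed: int | None = None,
) -> list[Word]:
    """Construct 4 words: 2 cued (with the requested harmony) and 2 uncued.

    All 12 syllables are pairwise distinct across the four words, which is
    what forces the within-word syllable TP to 1 in any stream built from
    them.  Cued words carry ``role_of_cued``; the uncued pair carries the
    other role.

    Raises
    ------
    InventoryError
        If fewer than 3 consonants or 3 vowels are available, or distinct
        syllables cannot be constructed.
    """
    if harmony_type not in ("vowel", "consonant"):
        raise ValueError(f"harmony_type must be vowel|consonant, got {harmony_type!r}")
    if role_of_cued not in ("object", "action"):
        raise ValueError(f"role_of_cued must be object|action, got {role_of_cued!r}")
    consonants = list(dict.fromkeys(consonants))
    vowels = list(dict.fromkeys(vowels))
    if len(consonants) < 3 or len(vowels) < 3:
        raise InventoryError(
            "inventory exhausted: need at least 3 consonants and 3 vowels, "
            f"got {len(consonants)} consonants / {len(vowels)} vowels"
        )
    rng = np.random.default_rng(rng_seed)

    for _ in range(200):  # rejection loop over random draws
        used: set[str] = set()
        words: list[Word] = []
        ok = True

        # two cued words, each harmony-legal
        if harmony_type == "vowel":
            if len(vowels) < 2:
                ok = False
            else:
                vs = rng.choice(len(vowels), size=2, replace=False)
                for k, vi in enumerate(vs):
                    cs = rng.choice(len(consonants), size=3, replace=False)
                    syls = tuple(consonants[c] + vowels[vi] for c in cs)
                    if len(set(syls)) != 3 or used & set(syls):
                        ok = False
                        break
                    used |= set(syls)
                    words.append(
                        Word(f"cued{k + 1}", syls, "vowel", role_of_cued)
                    )
        else:
            cs2 = rng.choice(len(consonants), size=2, replace=False)
            for k, ci in enumerate(cs2):
                vs3 = rng.choice(len(vowels), size=3, replace=False)
                syls = tuple(consonants[ci] + vowels[v] for v in vs3)
                if len(set(syls)) != 3 or used & set(syls):
                    ok = False
                    break
                used |= set(syls)
                words.append(
                    Word(f"cued{k + 1}", syls, "consonant", role_of_cued)
                )
        if not ok:
            continue

        # two uncued words: no repeated vowel or consonant triple
        uncued_role = "action" if role_of_cued == "object" else "object"
        for k in range(2):
            for _try in range(100):
                cs = rng.choice(len(consonants), size=3, replace=False)
                vs = rng.choice(len(vowels), size=3, replace=False)
                syls = tuple(consonants[c] + vowels[v] for c, v in zip(cs, vs))
                if len(set(syls)) == 3 and not (used & set(syls)):
                    used |= set(syls)
                    words.append(Word(f"uncued{k + 1}", syls, "none", uncued_role))
                    break
            else:
                ok = False
                break
        if ok and len(words) == 4:
            return words

    raise InventoryError("inventory exhausted: could not build 12 distinct syllables")


@dataclass
class DesignConfig:
    """Full parameterization of one stream/experiment version."""

    words: list[Word]
    pairing: dict[str, str]  # object word -> woman; action word -> gesture
    cued_words: tuple[str, str]
    n_repetitions_per_word: int = 24
    consonant_ms: float = 170.0
    vowel_ms: float = 286.0
    version_id: int = 1
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        roles = [w.word_role for w in self.words]
        if roles.count("object") != 2 or roles.count("action") != 2:
            raise ValueError("need exactly 2 object-words and 2 action-words")
        labels = {w.label for w in self.words}
        if set(self.pairing) != labels:
            raise ValueError("pairing must map every word label")
        cued = [w for w in self.words if w.label in self.cued_words]
        if len(cued) != 2:
            raise ValueError("cued_words must name exactly 2 of the words")
        if len({w.harmony for w in cued}) != 1 or cued[0].harmony == "none":
            raise ValueError("the 2 cued words must share a harmony type")
        if len({w.word_role for w in cued}) != 1:
            raise ValueError("the 2 cued words must share a word role")
        womans = {self.pairing[w.label] for w in self.object_words}
        gestures = {self.pairing[w.label] for w in self.action_words}
        if womans != {"A", "B"}:
            raise ValueError("object-words must be paired with women A and B")
        if gestures != {"up_down", "left_right"}:
            raise ValueError("action-words must be paired with the two gestures")
        if not (1 <= self.version_id <= 3):
            raise ValueError("version_id must be 1..3")

    @property
    def object_words(self) -> list[Word]:
        return [w for w in self.words if w.word_role == "object"]

    @property
    def action_words(self) -> list[Word]:
        return [w for w in self.words if w.word_role == "action"]

    @property
    def word_duration_ms(self) -> float:
        return 3.0 * (self.consonant_ms + self.vowel_ms)

    def word(self, label: str) -> Word:
        for w in self.words:
            if w.label == label:
                return w
        raise KeyError(label)


def _random_eulerian_circuit(
    edges: Iterable[tuple], start, rng: np.random.Generator
) -> list:
    """Node sequence of a random Eulerian circuit (Hierholzer on shuffled
    adjacency lists). The returned list omits the repeated final node."""
    adj: dict = defaultdict(list)
    for u, v in edges:
        adj[u].append(v)
    for u in adj:
        order = rng.permutation(len(adj[u]))
        adj[u] = [adj[u][i] for i in order]
    stack = [start]
    circuit: list = []
    while stack:
        u = stack[-1]
        if adj[u]:
            stack.append(adj[u].pop())
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    if circuit[0] != circuit[-1]:
        raise RuntimeError("graph is not Eulerian")
    return circuit[:-1]


def _image_for(config: DesignConfig, word: Word, woman: str) -> ImageToken:
    if word.word_role == "object":
        return ImageToken("picture", config.pairing[word.label])
    return ImageToken("video", woman, config.pairing[word.label])


def build_familiarization_sequence(
    config: DesignConfig, rng_seed: int | None = None
) -> list[tuple[Word, ImageToken]]:
    """Randomized familiarization sequence with exact circular TP balance.

    The sequence strictly alternates object-word (picture) and action-word
    (video) events; each picture is immediately followed by a video of the
    same woman.  Each word occurs exactly ``n_repetitions_per_word`` times.
    Treated as a cycle, every allowed word-to-word transition occurs exactly
    n/2 times (between-word TP 0.5).  When n is divisible by 8 the circuit
    is built on (object, action) pair types, which additionally balances
    every image-to-image transition (image TP 0.5 exactly).
    """
    n = config.n_repetitions_per_word
    if n % 2 != 0:
        raise ValueError("n_repetitions_per_word must be even for exact TP balance")
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    objs = config.object_words
    acts = config.action_words

    if n % 8 == 0:
        # pair-type graph: nodes (i, j) = (object index, action index);
        # n/8 parallel edges between every ordered pair of nodes
        nodes = [(i, j) for i in range(2) for j in range(2)]
        edges = [(u, v) for u in nodes for v in nodes for _ in range(n // 8)]
        start = nodes[rng.integers(len(nodes))]
        pairs = _random_eulerian_circuit(edges, start, rng)
        seq: list[tuple[Word, ImageToken]] = []
        for i, j in pairs:
            obj, act = objs[i], acts[j]
            woman = config.pairing[obj.label]
            seq.append((obj, _image_for(config, obj, woman)))
            seq.append((act, _image_for(config, act, woman)))
        return seq

    # word-level balance only: n/2 parallel edges object->action and back
    edges = [
        (o.label, a.label) for o in objs for a in acts for _ in range(n // 2)
    ] + [(a.label, o.label) for o in objs for a in acts for _ in range(n // 2)]
    start = objs[rng.integers(2)].label
    labels = _random_eulerian_circuit(edges, start, rng)
    seq = []
    woman = "A"
    for lab in labels:
        w = config.word(lab)
        if w.word_role == "object":
            woman = config.pairing[lab]
        seq.append((w, _image_for(config, w, woman)))
    return seq


@dataclass(frozen=True)
class StreamEvent:
    word: str
    image: ImageToken
    onset_ms: float
    offset_ms: float
    syllable_onsets_ms: tuple[float, float, float]


@dataclass
class StreamSpec:
    """The timed familiarization schedule."""

    events: list[StreamEvent]
    total_duration_ms: float
    words: dict[str, Word] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "total_duration_ms": self.total_duration_ms,
            "events": [
                {
                    "word": e.word,
                    "image": e.image.as_str(),
                    "onset_ms": e.onset_ms,
                    "offset_ms": e.offset_ms,
                    "syllable_onsets_ms": list(e.syllable_onsets_ms),
                }
                for e in self.events
            ],
            "words": {
                lab: {
                    "syllables": list(w.syllables),
                    "harmony": w.harmony,
                    "word_role": w.word_role,
                }
                for lab, w in self.words.items()
            },
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "StreamSpec":
        payload = json.loads(text)
        events = []
        for e in payload["events"]:
            kind, woman, gesture = e["image"].split(":")
            events.append(
                StreamEvent(
                    word=e["word"],
                    image=ImageToken(kind, woman, gesture),
                    onset_ms=e["onset_ms"],
                    offset_ms=e["offset_ms"],
                    syllable_onsets_ms=tuple(e["syllable_onsets_ms"]),
                )
            )
        words = {
            lab: Word(lab, tuple(d["syllables"]), d["harmony"], d["word_role"])
            for lab, d in payload.get("words", {}).items()
        }
        return cls(events=events, total_duration_ms=payload["total_duration_ms"], words=words)

    def to_tsv(self) -> str:
        lines = ["word\timage\tonset_ms\toffset_ms\tsyl1_ms\tsyl2_ms\tsyl3_ms"]
        for e in self.events:
            s = "\t".join(
                [e.word, e.image.as_str(), f"{e.onset_ms:g}", f"{e.offset_ms:g}"]
                + [f"{t:g}" for t in e.syllable_onsets_ms]
            )
            lines.append(s)
        return "\n".join(lines) + "\n"


def schedule_stream(
    sequence: Sequence[tuple[Word, ImageToken]], config: DesignConfig
) -> StreamSpec:
    """Lay the event sequence on the timing grid.

    Each word lasts 3*(consonant_ms + vowel_ms); events are contiguous, and
    syllable onsets sit at 0, 1, 2 syllable durations within the event.
    """
    syl_ms = config.consonant_ms + config.vowel_ms
    dur = 3.0 * syl_ms
    events = []
    t = 0.0
    for word, image in sequence:
        events.append(
            StreamEvent(
                word=word.label,
                image=image,
                onset_ms=t,
                offset_ms=t + dur,
                syllable_onsets_ms=(t, t + syl_ms, t + 2 * syl_ms),
            )
        )
        t += dur
    return StreamSpec(
        events=events,
        total_duration_ms=t,
        words={w.label: w for w in config.words},
    )


@dataclass
class TransitionTable:
    """Empirical first-order transition probabilities in a stream."""

    word_tp: dict[tuple[str, str], float]
    syllable_tp: dict[tuple[str, str], float]
    image_tp: dict[tuple[str, str], float]
    within_word_pairs: set[tuple[str, str]]

    def within_word_syllable_tps(self) -> dict[tuple[str, str], float]:
        return {k: v for k, v in self.syllable_tp.items() if k in self.within_word_pairs}

    def between_word_syllable_tps(self) -> dict[tuple[str, str], float]:
        return {
            k: v for k, v in self.syllable_tp.items() if k not in self.within_word_pairs
        }


def _tp_from_pairs(pairs: list[tuple]) -> dict[tuple, float]:
    counts: dict[tuple, int] = defaultdict(int)
    row: dict = defaultdict(int)
    for a, b in pairs:
        counts[(a, b)] += 1
        row[a] += 1
    return {k: c / row[k[0]] for k, c in counts.items()}


def compute_transition_table(
    sequence, words: dict[str, Word] | None = None, circular: bool = True
) -> TransitionTable:
    """Word-, syllable- and image-level TPs of a familiarization sequence.

    Accepts a list of ``(Word, ImageToken)`` pairs, a list of ``Word``, or a
    :class:`StreamSpec`.  With ``circular=True`` (default) the last element
    is treated as preceding the first, matching the Eulerian construction so
    that the designed balance is exact.
    """
    if isinstance(sequence, StreamSpec):
        words = words or sequence.words
        items = [(words[e.word], e.image) for e in sequence.events]
    else:
        items = [it if isinstance(it, tuple) else (it, None) for it in sequence]
    if not items:
        raise ValueError("empty sequence")

    word_seq = [w.label for w, _ in items]
    syl_seq: list[str] = []
    within: set[tuple[str, str]] = set()
    for w, _ in items:
        syl_seq.extend(w.syllables)
        within.add((w.syllables[0], w.syllables[1]))
        within.add((w.syllables[1], w.syllables[2]))
    img_seq = [im.as_str() for _, im in items if im is not None]

    def adjacent(seq: list) -> list[tuple]:
        ps = list(zip(seq, seq[1:]))
        if circular and len(seq) > 1:
            ps.append((seq[-1], seq[0]))
        return ps

    return TransitionTable(
        word_tp=_tp_from_pairs(adjacent(word_seq)) if len(word_seq) > 1 else {},
        syllable_tp=_tp_from_pairs(adjacent(syl_seq)),
        image_tp=_tp_from_pairs(adjacent(img_seq)) if len(img_seq) > 1 else {},
        within_word_pairs=within,
    )


# --- test phase -----------------------------------------------------------

TRIAL_END_MS = 4700.0
SILENCE_MS = 1000.0


@dataclass(frozen=True)
class TestTrial:
    """One preferential-looking test trial.

    t = 0 is the onset of the lateralized images, synchronized with the
    second presentation of the word; the trial ends at 4700 ms.
    """

    index: int
    unique_id: str
    tested_word: str
    correct_image: ImageToken
    incorrect_image: ImageToken
    correct_side: str  # "left" | "right"
    timeline: tuple[tuple[str, float, float], ...]  # (event, onset, offset)

    @property
    def end_ms(self) -> float:
        return TRIAL_END_MS


@dataclass
class TestTrialSchedule:
    trials: list[TestTrial]

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "index": t.index,
                    "unique_id": t.unique_id,
                    "tested_word": t.tested_word,
                    "correct_image": t.correct_image.as_str(),
                    "incorrect_image": t.incorrect_image.as_str(),
                    "correct_side": t.correct_side,
                    "timeline": [list(ev) for ev in t.timeline],
                }
                for t in self.trials
            ],
            indent=1,
        )


def _trial_timeline(config: DesignConfig, attractor_ms: float) -> tuple:
    wd = config.word_duration_ms
    squares_on = -(wd + 2 * SILENCE_MS)  # empty squares, 1 s before word 1
    return (
        ("attractor", squares_on - attractor_ms, squares_on),
        ("empty_squares", squares_on, 0.0),
        ("word_1", squares_on + SILENCE_MS, squares_on + SILENCE_MS + wd),
        ("images_on", 0.0, TRIAL_END_MS),
        ("word_2", 0.0, wd),
        ("word_3", wd + SILENCE_MS, 2 * wd + SILENCE_MS),
        ("trial_end", TRIAL_END_MS, TRIAL_END_MS),
    )


def build_test_trials(
    config: DesignConfig,
    rng_seed: int | None = None,
    attractor_ms: float = 1500.0,
    max_run: int = 2,
) -> TestTrialSchedule:
    """16 test trials: 8 unique trials (4 per cued word), each shown twice.

    The two lateral images differ only in the tested dimension: for an
    action-word trial, the two gestures performed by the same woman; for an
    object-word trial, the two women's pictures.  The correct side is
    counterbalanced 4/4 within each tested word, and the pseudorandom order
    avoids more than ``max_run`` consecutive trials sharing the tested word
    or the correct side.
    """
    rng = np.random.default_rng(config.rng_seed if rng_seed is None else rng_seed)
    cued = [config.word(lab) for lab in config.cued_words]
    timeline = _trial_timeline(config, attractor_ms)

    uniques: list[TestTrial] = []
    for w in cued:
        for vi, variant in enumerate(("A", "B")):
            for side in ("left", "right"):
                if w.word_role == "action":
                    g = config.pairing[w.label]
                    g_other = "left_right" if g == "up_down" else "up_down"
                    correct = ImageToken("video", variant, g)
                    incorrect = ImageToken("video", variant, g_other)
                else:
                    woman = config.pairing[w.label]
                    other = "B" if woman == "A" else "A"
                    correct = ImageToken("picture", woman)
                    incorrect = ImageToken("picture", other)
                uniques.append(
                    TestTrial(
                        index=-1,
                        unique_id=f"{w.label}|v{vi + 1}|{side}",
                        tested_word=w.label,
                        correct_image=correct,
                        incorrect_image=incorrect,
                        correct_side=side,
                        timeline=timeline,
                    )
                )

    pool = uniques + uniques
    for _ in range(10_000):
        order = [pool[i] for i in rng.permutation(len(pool))]
        words_ok = _max_run_len([t.tested_word for t in order]) <= max_run
        sides_ok = _max_run_len([t.correct_side for t in order]) <= max_run
        if words_ok and sides_ok:
            break
    else:  # pragma: no cover - constraint is easily satisfiable
        raise RuntimeError("could not satisfy pseudorandomization constraints")
    trials = [replace(t, index=i) for i, t in enumerate(order)]
    return TestTrialSchedule(trials=trials)


def _max_run_len(seq: list) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


def counterbalance_versions(base: DesignConfig) -> list[DesignConfig]:
    """Three versions differing only in the word-image pairing map.

    Across the versions every object-word appears with both women and every
    action-word with both gestures; deterministic in the version number.
    """
    objs = [w.label for w in base.object_words]
    acts = [w.label for w in base.action_words]
    o_pairings = [
        {objs[0]: "A", objs[1]: "B"},
        {objs[0]: "B", objs[1]: "A"},
    ]
    a_pairings = [
        {acts[0]: "up_down", acts[1]: "left_right"},
        {acts[0]: "left_right", acts[1]: "up_down"},
    ]
    combos = [(0, 0), (1, 0), (0, 1)]  # three distinct maps covering both levels
    out = []
    for vid, (oi, ai) in enumerate(combos, start=1):
        pairing = {**o_pairings[oi], **a_pairings[ai]}
        out.append(replace(base, pairing=pairing, version_id=vid))
    return out
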