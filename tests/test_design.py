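"""Stimulus-design invariants: word construction, stream TP balance,
timing grid, test-trial counterbalancing and version rotation."""

import itertools
from collections import Counter

import numpy as np
import pytest

import lexigaze as lg
from lexigaze.design import (
    DEFAULT_CONSONANTS,
    DEFAULT_VOWELS,
    InventoryError,
    StreamSpec,
    _max_run_len,
)


# --- words ----------------------------------------------------------------

@pytest.mark.parametrize("harmony,role", [("vowel", "action"), ("consonant", "object"),
                                          ("vowel", "object"), ("consonant", "action")])
def test_make_words_invariants(harmony, role):
    words = lg.make_words(harmony, role, rng_seed=7)
    assert len(words) == 4
    all_syls = [s for w in words for s in w.syllables]
    assert len(set(all_syls)) == 12, "all 12 syllables must be pairwise distinct"
    cued = [w for w in words if w.harmony != "none"]
    uncued = [w for w in words if w.harmony == "none"]
    assert len(cued) == 2 and len(uncued) == 2
    for w in cued:
        assert w.harmony == harmony
        assert w.word_role == role
        if harmony == "vowel":
            assert len({s[1] for s in w.syllables}) == 1
        else:
            assert len({s[0] for s in w.syllables}) == 1
    other = "object" if role == "action" else "action"
    assert all(w.word_role == other for w in uncued)


def test_make_words_small_inventory_errors():
    with pytest.raises(InventoryError):
        lg.make_words("vowel", "action", vowels=("a", "e"), rng_seed=0)
    with pytest.raises(InventoryError):
        lg.make_words("consonant", "object", consonants=("b", "d"), rng_seed=0)


# --- familiarization sequence --------------------------------------------

def test_sequence_counts_and_balance(design):
    seq = lg.build_familiarization_sequence(design, rng_seed=3)
    assert len(seq) == 96
    counts = Counter(w.label for w, _ in seq)
    assert all(c == 24 for c in counts.values())
    # circular word transitions: every allowed one exactly 12 times
    labels = [w.label for w, _ in seq]
    pairs = Counter(zip(labels, labels[1:] + labels[:1]))
    assert all(c == 12 for c in pairs.values())
    assert len(pairs) == 8


def test_sequence_alternation_and_same_woman(design):
    seq = lg.build_familiarization_sequence(design, rng_seed=9)
    kinds = [im.kind for _, im in seq]
    assert all(a != b for a, b in zip(kinds, kinds[1:]))
    assert kinds[0] == "picture"
    for (w1, im1), (w2, im2) in zip(seq, seq[1:]):
        if im1.kind == "picture":
            assert im2.kind == "video"
            assert im2.woman == im1.woman, "picture must be followed by the same woman's video"
    for w, im in seq:
        if w.word_role == "object":
            assert im.kind == "picture" and im.woman == design.pairing[w.label]
        else:
            assert im.kind == "video" and im.gesture == design.pairing[w.label]


def test_sequence_odd_repetitions_rejected(design):
    from dataclasses import replace

    with pytest.raises(ValueError):
        lg.build_familiarization_sequence(
            replace(design, n_repetitions_per_word=3), rng_seed=0
        )


def test_sequence_randomized_across_seeds(design):
    a = lg.build_familiarization_sequence(design, rng_seed=1)
    b = lg.build_familiarization_sequence(design, rng_seed=2)
    assert [w.label for w, _ in a] != [w.label for w, _ in b]
    # and deterministic for equal seeds
    c = lg.build_familiarization_sequence(design, rng_seed=1)
    assert [w.label for w, _ in a] == [w.label for w, _ in c]


def _enumerate_balanced_8(design):
    """Brute-force oracle: all 8-event circular sequences with each word
    twice, object/action alternation, and every allowed transition once."""
    objs = [w.label for w in design.object_words]
    acts = [w.label for w in design.action_words]
    valid = set()
    for opos in itertools.permutations(objs + objs):
        for apos in itertools.permutations(acts + acts):
            seq = [x for pair in zip(opos, apos) for x in pair]
            pairs = Counter(zip(seq, seq[1:] + seq[:1]))
            if len(pairs) == 8 and all(c == 1 for c in pairs.values()):
                valid.add(tuple(seq))
    return valid


def test_two_repetition_sequence_matches_enumeration(design):
    from dataclasses import replace

    oracle = _enumerate_balanced_8(design)
    assert oracle, "the balanced-8 family must be non-empty"
    for seed in range(10):
        seq = lg.build_familiarization_sequence(
            replace(design, n_repetitions_per_word=2), rng_seed=seed
        )
        assert len(seq) == 8
        assert tuple(w.label for w, _ in seq) in oracle


# --- timing grid ----------------------------------------------------------

def test_schedule_timing_default(design):
    seq = lg.build_familiarization_sequence(design, rng_seed=3)
    stream = lg.schedule_stream(seq, design)
    assert stream.total_duration_ms == 96 * 3 * (170 + 286) == 131328
    e0 = stream.events[0]
    assert e0.offset_ms - e0.onset_ms == 1368
    assert np.allclose(np.diff(e0.syllable_onsets_ms), 456)
    onsets = [e.onset_ms for e in stream.events]
    offsets = [e.offset_ms for e in stream.events]
    assert onsets[1:] == offsets[:-1], "events are contiguous"


def test_schedule_single_and_degenerate_timing(design):
    from dataclasses import replace

    seq = lg.build_familiarization_sequence(design, rng_seed=3)[:1]
    stream = lg.schedule_stream(seq, design)
    assert stream.total_duration_ms == 1368
    cfg = replace(design, consonant_ms=0.0, vowel_ms=100.0)
    stream = lg.schedule_stream(seq, cfg)
    assert stream.events[0].offset_ms - stream.events[0].onset_ms == 300


def test_stream_json_roundtrip(design):
    seq = lg.build_familiarization_sequence(design, rng_seed=4)
    stream = lg.schedule_stream(seq, design)
    back = StreamSpec.from_json(stream.to_json())
    assert back.total_duration_ms == stream.total_duration_ms
    assert back.events == stream.events


# --- transition table -----------------------------------------------------

def test_transition_table_stream_values(design):
    seq = lg.build_familiarization_sequence(design, rng_seed=3)
    tt = lg.compute_transition_table(seq)
    assert set(tt.within_word_syllable_tps().values()) == {1.0}
    assert set(np.round(list(tt.image_tp.values()), 12)) == {0.5}
    assert set(np.round(list(tt.word_tp.values()), 12)) == {0.5}
    # rows sum to 1 over observed successors
    for table in (tt.word_tp, tt.syllable_tp, tt.image_tp):
        rows = {}
        for (a, _), p in table.items():
            rows[a] = rows.get(a, 0.0) + p
        assert np.allclose(list(rows.values()), 1.0)


def test_transition_table_degenerate_and_empty(design):
    w1 = design.words[0]
    tt = lg.compute_transition_table([w1, w1])
    assert tt.word_tp[(w1.label, w1.label)] == 1.0
    with pytest.raises(ValueError):
        lg.compute_transition_table([])


# --- test trials ----------------------------------------------------------

def test_test_trials_counts_and_side_balance(design, schedule):
    trials = schedule.trials
    assert len(trials) == 16
    by_word = Counter(t.tested_word for t in trials)
    assert all(c == 8 for c in by_word.values())
    by_word_side = Counter((t.tested_word, t.correct_side) for t in trials)
    assert all(c == 4 for c in by_word_side.values())
    uniq = Counter(t.unique_id for t in trials)
    assert len(uniq) == 8 and all(c == 2 for c in uniq.values())


def test_test_trials_timeline_and_repeats(design, schedule):
    for t in schedule.trials:
        tl = dict((name, (a, b)) for name, a, b in t.timeline)
        assert tl["images_on"] == (0.0, 4700.0)
        assert tl["word_2"][0] == 0.0
        assert tl["word_3"][0] == pytest.approx(1368 + 1000)
        assert t.end_ms == 4700.0
    # the two repeats of a unique trial differ only in ordinal position
    by_uid = {}
    for t in schedule.trials:
        by_uid.setdefault(t.unique_id, []).append(t)
    for a, b in by_uid.values():
        assert (a.tested_word, a.correct_image, a.incorrect_image, a.correct_side) == (
            b.tested_word, b.correct_image, b.incorrect_image, b.correct_side)


def test_test_trials_lateral_images_differ_only_in_tested_dimension(design, object_design):
    for cfg in (design, object_design):
        sched = lg.build_test_trials(cfg, rng_seed=2)
        for t in sched.trials:
            c, i = t.correct_image, t.incorrect_image
            role = cfg.word(t.tested_word).word_role
            if role == "action":
                assert c.kind == i.kind == "video"
                assert c.woman == i.woman and c.gesture != i.gesture
            else:
                assert c.kind == i.kind == "picture"
                assert c.woman != i.woman


@pytest.mark.parametrize("seed", range(8))
def test_test_trials_pseudorandom_run_limits(design, seed):
    sched = lg.build_test_trials(design, rng_seed=seed)
    assert _max_run_len([t.tested_word for t in sched.trials]) <= 2
    assert _max_run_len([t.correct_side for t in sched.trials]) <= 2


# --- counterbalancing -----------------------------------------------------

def test_counterbalance_versions(design):
    versions = lg.counterbalance_versions(design)
    assert len(versions) == 3
    maps = [tuple(sorted(v.pairing.items())) for v in versions]
    assert len(set(maps)) == 3, "pairing maps must be pairwise distinct"
    # each object-word sees both women somewhere across versions
    for w in design.object_words:
        assert {v.pairing[w.label] for v in versions} == {"A", "B"}
    again = lg.counterbalance_versions(design)
    assert [v.pairing for v in again] == [v.pairing for v in versions]
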