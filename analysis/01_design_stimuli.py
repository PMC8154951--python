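"""Generate the audiovisual stimulus design: words, familiarization stream,
transition-probability audit and test-trial schedule.

Writes results/design/{stream.json,test_trials.json,transition_probabilities.csv}.
"""

import argparse
import csv
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

import numpy as np

import lexigaze as lg


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--harmony", choices=["vowel", "consonant"], default="vowel")
    ap.add_argument("--cued-role", choices=["object", "action"], default="action")
    ap.add_argument("--out-dir", type=Path,
                    default=Path(__file__).resolve().parent.parent / "results" / "design")
    args = ap.parse_args()

    rng = np.random.default_rng(args.seed)
    design = lg.default_design(args.harmony, args.cued_role,
                               rng_seed=int(rng.integers(2**31)))
    seq = lg.build_familiarization_sequence(design, rng_seed=int(rng.integers(2**31)))
    stream = lg.schedule_stream(seq, design)
    schedule = lg.build_test_trials(design, rng_seed=int(rng.integers(2**31)))
    tab = lg.compute_transition_table(seq)

    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "stream.json").write_text(stream.to_json())
    (args.out_dir / "test_trials.json").write_text(schedule.to_json())
    with open(args.out_dir / "transition_probabilities.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["level", "from", "to", "tp", "within_word"])
        for (a, b), v in sorted(tab.syllable_tp.items()):
            w.writerow(["syllable", a, b, v, (a, b) in tab.within_word_pairs])
        for (a, b), v in sorted(tab.word_tp.items()):
            w.writerow(["word", a, b, v, ""])
        for (a, b), v in sorted(tab.image_tp.items()):
            w.writerow(["image", a, b, v, ""])

    print(f"words: {[w.label for w in design.words]}")
    print(f"stream: {len(stream.events)} events, {stream.total_duration_ms:.0f} ms")
    print(f"syllable TPs within/between: "
          f"{sorted(set(tab.within_word_syllable_tps().values()))} / "
          f"{sorted(set(tab.between_word_syllable_tps().values()))}")
    print(f"test trials: {len(schedule.trials)}; wrote {args.out_dir}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
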