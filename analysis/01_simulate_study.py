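#!/usr/bin/env python
"""Generate the working synthetic study.

A seeded 9-case / 3-control study on a 1600-antigen slide, with 20 planted
case-specific autoantibody elevations (fold 5, penetrance 0.5) among 1580
null probes.  Writes GAL + GPR files, the sample sheet and the ground truth
under results/study/.
"""

from pathlib import Path

from immunoarray.synthetic_data import SyntheticConfig, generate_study, with_planted

OUT = Path(__file__).resolve().parent.parent / "results" / "study"
SEED = 20260926


def main() -> None:
    cfg = with_planted(
        SyntheticConfig(seed=SEED), n_planted=20, fold=5.0, penetrance=0.5
    )
    sheet = generate_study(cfg, OUT)
    print(f"wrote {len(sheet.rows)} slides ({len(sheet.case_ids)} cases, "
          f"{len(sheet.control_ids)} controls) to {OUT}")
    print(f"planted: {len(cfg.planted)} biomarkers, fold {cfg.planted[0].fold}, "
          f"penetrance {cfg.planted[0].penetrance}")


if __name__ == "__main__":
    main()
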