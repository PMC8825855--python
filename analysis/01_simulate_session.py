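#!/usr/bin/env python
"""Generate the study's synthetic sessions and write them to disk.

Produces the default rate-coding session (60 neurons, 40 sequences,
lag gain rho = 0.6) and a theta session (with LFP) used by the later
stages, under results/sessions/.
"""

import sys
from pathlib import Path

from seqmem import GeneratorConfig, simulate_session, write_session

# raw session dumps are large and regenerable: they live under scratch/
OUT = Path(__file__).resolve().parents[1] / "scratch" / "sessions"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    cfg = GeneratorConfig()
    session, gt = simulate_session(cfg, seed=seed, include_lfp=False)
    write_session(session, OUT / "rate_session")
    gt.to_json(OUT / "rate_session" / "ground_truth.json")
    print(f"rate session: {session.n_neurons} neurons, {len(session.trials)} trials "
          f"({session.trials.in_seq.sum()} InSeq, "
          f"{(~session.trials.correct).sum()} incorrect)")

    # probe-rich theta session: more OutSeq probes and errors, so the
    # trial-type comparisons have material to work with
    cfg_th = GeneratorConfig(n_neurons=40, n_sequences=30)
    cfg_th.p_outseq = (0.25, 0.25, 0.15, 0.1)
    theta, gt_th = simulate_session(cfg_th, seed=seed + 1, include_lfp=True)
    write_session(theta, OUT / "theta_session")
    gt_th.to_json(OUT / "theta_session" / "ground_truth.json")
    print(f"theta session: {theta.n_neurons} neurons, {len(theta.trials)} trials, "
          f"{len(theta.lfp)} LFP channels at {theta.sample_rate_lfp:.0f} Hz")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
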