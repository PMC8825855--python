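#!/usr/bin/env python
"""Latent representation: autoencoder embeddings of the four behavior-
matched windows, k-NN separability of stimulus / temporal order / outcome,
and the Mahalanobis cluster-lag trend.

Reads scratch/sessions/rate_session, writes results/latent/.
"""

from pathlib import Path

import pandas as pd

from seqmem import TrialSelection, load_session, select_trials
from seqmem.latent import DEFAULT_WINDOWS, cluster_lag_distance, embed_window, knn_separability

ROOT = Path(__file__).resolve().parents[1]
SESSIONS = ROOT / "scratch" / "sessions"
OUT = ROOT / "results" / "latent"

LABELS = {
    "stimulus": (TrialSelection(in_seq=True, correct=True, odors=("B", "C", "D")),
                 lambda df: df.odor),
    "temporal_order": (TrialSelection(correct=True, odors=("B", "C", "D")),
                       lambda df: df.in_seq.map({True: "InSeq", False: "OutSeq"})),
    "outcome": (TrialSelection(),
                lambda df: df.correct.map({True: "correct", False: "incorrect"})),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    session = load_session(SESSIONS / "rate_session")

    rows = []
    for window_id in DEFAULT_WINDOWS:
        for label, (crit, labeller) in LABELS.items():
            sel = select_trials(session.trials, crit).reset_index(drop=True)
            y = labeller(sel).to_numpy()
            if pd.Series(y).value_counts().min() < 4:
                print(f"{window_id}/{label}: too few trials per class, skipped")
                continue
            emb = embed_window(session, sel, window_id, seed=7,
                               encoder_widths=(128, 128), epochs=80)
            res = knn_separability(emb, y, n_perm=100, seed=7)
            rows.append(dict(window=window_id, label=label, **{
                "accuracy": res["accuracy"], "chance_upper": res["chance_ci"][1],
                "significant": res["significant"], "n_test": res["n_test"]}))
            star = "*" if res["significant"] else " "
            print(f"{window_id:>14} {label:>14}: accuracy {res['accuracy']:.3f} "
                  f"(chance upper {res['chance_ci'][1]:.3f}){star}")
    pd.DataFrame(rows).to_csv(OUT / "knn_separability.csv", index=False)

    sel = select_trials(session.trials, TrialSelection(
        in_seq=True, correct=True, odors=("B", "C", "D", "E"))).reset_index(drop=True)
    emb = embed_window(session, sel, "entry_250_500", seed=7,
                       encoder_widths=(128, 128), epochs=80)
    table, summary = cluster_lag_distance(emb, session.trials, "inseq")
    table.to_csv(OUT / "cluster_lag_distance.csv", index=False)
    print(f"cluster distance vs lag ({summary['metric']}): slope "
          f"{summary['trend_slope']:.3f}, trend p = {summary['trend_p']:.2e}; "
          f"means {dict((k, round(v, 3)) for k, v in summary['mean_by_lag'].items())}")


if __name__ == "__main__":
    main()
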