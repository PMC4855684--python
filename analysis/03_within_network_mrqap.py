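"""Within-classroom MRQAP models with directional backward elimination.

Each class's allocation matrix is regressed on relationship strength,
reciprocation and the gender-giving/receiving matrices using MRQAP with
double semipartialing, then non-significant terms are removed one at a
time (two-tailed p closest to 1 first, refitting with fresh permutations
after every drop).  Writes per-class model tables and elimination traces
under results/tables/.

Run after 01_simulate_study.py:  python analysis/03_within_network_mrqap.py
"""

from pathlib import Path

import pandas as pd

import dyadqap as dq
from dyadqap.pipeline import DEFAULT_HYPOTHESES, model_table, trace_table

DATA = Path("results/data")
OUT = Path("results/tables")
SEED = 11
N_PERM = 2000


def load_group(gid: str) -> dict[str, dq.DyadicMatrix]:
    Y = dq.read_adjacency_csv(DATA / f"allocation_{gid}.csv", kind="allocation")
    S = dq.read_adjacency_csv(DATA / f"strength_{gid}.csv", kind="strength")
    R = dq.read_adjacency_csv(DATA / f"reciprocation_{gid}.csv", kind="reciprocation")
    actors = pd.read_csv(DATA / f"actors_{gid}.csv")
    gender = pd.Series(actors["gender"].to_numpy(float),
                       index=actors["actor_id"].astype(str))
    return {
        "Y": Y, "strength": S, "reciprocation": R,
        "gender_giving": dq.build_attribute_matrix(Y.actors, gender, "giving"),
        "gender_receiving": dq.build_attribute_matrix(Y.actors, gender, "receiving"),
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    for gi, gid in enumerate(("g0", "g1")):
        mats = load_group(gid)
        Y = mats.pop("Y")
        hyps = {k: DEFAULT_HYPOTHESES.get(k, 0) for k in mats}

        def fit(terms, seed):
            return dq.dsp_test(Y, {t: mats[t] for t in terms},
                               dq.PermutationPlan(N_PERM, seed=seed),
                               {t: hyps[t] for t in terms})

        trace = dq.backward_eliminate(
            list(mats), fit,
            dq.SelectionConfig(directional_terms=hyps), seed=SEED + gi,
        )
        final = trace.final
        print(f"\nclass {gid}: final model "
              f"R2_adj = {final.r2_adj:.3f}, model p = {final.model_p:.4g}")
        for t in final.free_terms:
            tail = "one" if t.hypothesized_sign else "two"
            print(f"  {t.term:>18}: b = {t.estimate:+.3f} "
                  f"(std {t.standardized_estimate:+.3f}), p = {t.p:.4g} ({tail}-tailed)")
        for s in trace.steps:
            print(f"  dropped {s.dropped_term} (two-tailed p = {s.p_two_tailed:.3f})")
        model_table(final).to_csv(OUT / f"mrqap_{gid}.tsv", sep="\t", index=False)
        trace_table(trace).to_csv(OUT / f"mrqap_{gid}_trace.tsv", sep="\t", index=False)
    print(f"\ntables written to {OUT}/")


if __name__ == "__main__":
    main()
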