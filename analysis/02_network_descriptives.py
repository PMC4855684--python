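"""Compare network descriptives between the two simulated classrooms.

For each valued network variable (allocation, strength, reciprocation)
the two classes are compared with a t test whose standard errors come
from the vertex bootstrap and whose degrees of freedom equal the pooled
number of tie variables minus two.  Writes results/tables/density.tsv.

Run after 01_simulate_study.py:  python analysis/02_network_descriptives.py
"""

from pathlib import Path

import dyadqap as dq
from dyadqap.pipeline import density_table

DATA = Path("results/data")
OUT = Path("results/tables")
SEED = 7
N_BOOT = 2000


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    comparisons = []
    for var in ("allocation", "strength", "reciprocation"):
        A = dq.read_adjacency_csv(DATA / f"{var}_g0.csv")
        B = dq.read_adjacency_csv(DATA / f"{var}_g1.csv")
        c = dq.compare_densities(A, B, n_boot=N_BOOT, seed=SEED,
                                 ids=(f"{var}:g0", f"{var}:g1"))
        comparisons.append(c)
        verdict = "differ" if c.p_two_tailed < 0.05 else "do not differ"
        print(f"{var:>14}: density {c.density_a:.3f} vs {c.density_b:.3f}, "
              f"t({c.df}) = {c.t:.2f}, p = {c.p_two_tailed:.3f} -> groups {verdict}")
    density_table(comparisons).to_csv(OUT / "density.tsv", sep="\t", index=False)
    print(f"table written to {OUT / 'density.tsv'}")


if __name__ == "__main__":
    main()
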