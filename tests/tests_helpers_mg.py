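"""Shared builders for multigroup test scenarios."""

import numpy as np
import pandas as pd

import dyadqap as dq


def noise_groups(seed: int, n0: int = 9, n1: int = 8) -> list[dq.GroupData]:
    """Two classrooms whose allocations are pure noise (no true effects)."""
    schema = dq.ItemSchema.study1()
    out = []
    ss = np.random.SeedSequence(seed).spawn(2)
    for gid, n, code, child in (("g0", n0, 0, ss[0]), ("g1", n1, 1, ss[1])):
        s_net, s_y = (int(c.generate_state(1)[0] % 2**31) for c in child.spawn(2))
        actors = [f"{gid}_{i}" for i in range(n)]
        _, S = dq.simulate_strength_network(n, schema, 0.5, s_net, actors=actors)
        R = dq.build_reciprocation(S)
        rng = np.random.default_rng(s_y)
        Y = dq.DyadicMatrix(actors, rng.normal(3.0, 2.0, (n, n)), kind="allocation")
        out.append(dq.GroupData(
            group_id=gid,
            actors=pd.DataFrame({"actor_id": actors, "group_id": gid}),
            Y=Y,
            predictors={"strength": S, "reciprocation": R},
            group_code=code,
        ))
    return out
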