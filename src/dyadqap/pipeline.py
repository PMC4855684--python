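"""End-to-end study workflow.

The analysis strategy has three stages: (1) descriptive density
comparisons between classroom networks, (2) within-network MRQAP with
directional backward elimination in each class, and (3) a pooled
multigroup MRQAP with class fixed effects, group-interaction terms and
the same elimination rules.  Predictors enter the multigroup stage if
they (a) differed between groups in stage 1, (b) survived elimination in
any stage-2 model, or (c) are forced in to test a focal interaction.

``run_study`` is the library entry point; the report bundle it writes
(TSV tables, elimination traces, a manifest and a run log) is
deterministic given the configuration and seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .density import DensityComparison, compare_densities, pairwise_density_tests
from .multigroup import interaction_name, mg_fit
from .network_data import GroupData, ValidationError
from .qap import PermutationPlan, QapModelResult, dsp_test
from .selection import EliminationTrace, SelectionConfig, backward_eliminate

__all__ = ["StudyOptions", "StudyReport", "run_study"]

#: directional hypotheses used throughout: + stronger/reciprocated ties and
#: empathy increase giving; males and Machiavellian scorers give less.
DEFAULT_HYPOTHESES: dict[str, int] = {
    "strength": +1,
    "reciprocation": +1,
    "gender_giving": -1,
    "mach_giving": -1,
    "iri_ec_giving": +1,
    "iri_pt_giving": +1,
    interaction_name("strength"): +1,
    interaction_name("reciprocation"): +1,
    interaction_name("gender_giving"): -1,
    interaction_name("mach_giving"): -1,
    interaction_name("iri_ec_giving"): +1,
}


@dataclass(frozen=True)
class StudyOptions:
    predictors: tuple[str, ...] = ()            # default: all shared predictors
    hypotheses: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_HYPOTHESES))
    n_perm: int = 10_000
    n_boot: int = 1000
    alpha: float = 0.05
    seed: int = 0
    mg_method: str = "qap_y"
    focal_terms: frozenset[str] = frozenset({"reciprocation"})
    force_include: tuple[str, ...] = ()


@dataclass
class StudyReport:
    density: list[DensityComparison]
    group_models: dict[str, EliminationTrace]
    mg_model: EliminationTrace | None
    mg_initial_terms: tuple[str, ...]
    options: StudyOptions


def _shared_predictors(groups: Sequence[GroupData]) -> list[str]:
    names = set(groups[0].predictors)
    for g in groups[1:]:
        names &= set(g.predictors)
    # constant-per-group matrices (e.g. gender in a single-sex class) are unusable
    usable = []
    for nm in sorted(names):
        ok = all(np.nanstd(g.predictors[nm].offdiag_values()) > 0 for g in groups)
        if ok:
            usable.append(nm)
    return usable


def run_study(
    groups: Sequence[GroupData],
    options: StudyOptions | None = None,
    out_dir: str | Path | None = None,
) -> StudyReport:
    """Execute the three-stage workflow over a list of classroom networks.

    With ``out_dir`` set, writes ``report/*.tsv``, ``trace/*.tsv``,
    ``manifest.json`` and ``run.log`` under it.
    """
    options = options or StudyOptions()
    groups = list(groups)
    if not groups:
        raise ValidationError("no groups")
    predictors = list(options.predictors) or _shared_predictors(groups)
    hyps = dict(options.hypotheses)
    master = np.random.SeedSequence(options.seed)
    s_density, s_group, s_mg = (
        int(s.generate_state(1)[0] % 2**31) for s in master.spawn(3)
    )

    # Stage 1: density comparisons of the outcome and every network predictor
    density: list[DensityComparison] = []
    net_vars = ["allocation"] + predictors if len(groups) >= 2 else []
    differed: set[str] = set()
    for vi, var in enumerate(net_vars):
        nets = [
            (g.group_id, g.Y if var == "allocation" else g.predictors[var])
            for g in groups
        ]
        if len(nets) == 2:
            cmps = [
                compare_densities(
                    nets[0][1], nets[1][1], n_boot=options.n_boot,
                    seed=s_density + vi, ids=(nets[0][0], nets[1][0]),
                )
            ]
        else:
            cmps = pairwise_density_tests(
                nets, n_boot=options.n_boot, seed=s_density + vi,
                alpha=options.alpha,
            )
        for c in cmps:
            c = DensityComparison(**{**c.__dict__, "network_a": f"{var}:{c.network_a}",
                                     "network_b": f"{var}:{c.network_b}"})
            density.append(c)
            if c.significant and var != "allocation":
                differed.add(var)

    # Stage 2: within-network MRQAP + elimination
    sel = SelectionConfig(alpha=options.alpha, directional_terms=hyps)
    group_models: dict[str, EliminationTrace] = {}
    survivors: set[str] = set()
    for gi, g in enumerate(groups):
        def fit_one(terms: Sequence[str], seed: int, _g: GroupData = g) -> QapModelResult:
            return dsp_test(
                _g.Y,
                {t: _g.predictors[t] for t in terms},
                PermutationPlan(n_perm=options.n_perm, seed=seed),
                {t: hyps.get(t, 0) for t in terms},
            )

        trace = backward_eliminate(predictors, fit_one, sel, seed=s_group + gi)
        group_models[g.group_id] = trace
        survivors |= set(trace.final_terms)

    # Stage 3: pooled multigroup model
    mg_trace: EliminationTrace | None = None
    mg_terms: tuple[str, ...] = ()
    if len(groups) >= 2:
        base = sorted((differed | survivors | set(options.force_include)
                       | options.focal_terms) & set(predictors))
        initial = base + [interaction_name(t) for t in base]
        mg_terms = tuple(initial)
        mg_sel = SelectionConfig(
            alpha=options.alpha,
            directional_terms=hyps,
            forced_retention=frozenset(options.focal_terms),
        )

        def fit_mg(terms: Sequence[str], seed: int) -> QapModelResult:
            mains = [t for t in terms if not t.endswith(":group")]
            inters = [t[: -len(":group")] for t in terms if t.endswith(":group")]
            return mg_fit(
                groups, mains, inters,
                PermutationPlan(n_perm=options.n_perm, seed=seed),
                {t: hyps.get(t, 0) for t in terms},
                method=options.mg_method,
            )

        mg_trace = backward_eliminate(initial, fit_mg, mg_sel, seed=s_mg)

    report = StudyReport(
        density=density,
        group_models=group_models,
        mg_model=mg_trace,
        mg_initial_terms=mg_terms,
        options=options,
    )
    if out_dir is not None:
        _write_report(report, groups, Path(out_dir))
    return report


# ---------------------------------------------------------------------------
# Report serialization
# ---------------------------------------------------------------------------

def density_table(comparisons: Sequence[DensityComparison]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair": [f"{c.network_a} vs {c.network_b}" for c in comparisons],
            "density_a": [round(c.density_a, 6) for c in comparisons],
            "density_b": [round(c.density_b, 6) for c in comparisons],
            "se_a": [round(c.se_a, 6) for c in comparisons],
            "se_b": [round(c.se_b, 6) for c in comparisons],
            "t": [round(c.t, 4) for c in comparisons],
            "df": [c.df for c in comparisons],
            "p": [round(c.p_two_tailed, 6) for c in comparisons],
            "significant_after_bonferroni": [c.significant for c in comparisons],
        }
    )


def model_table(result: QapModelResult) -> pd.DataFrame:
    """Term table mirroring the published layout: coefficient, standardized
    coefficient (single-network models only), p-value and its tail."""
    rows = []
    for t in result.terms:
        rows.append(
            {
                "term": t.term,
                "b": round(t.estimate, 6),
                "b_std": "" if t.standardized_estimate is None
                else round(t.standardized_estimate, 6),
                "p": round(t.p, 6),
                "tail": "one" if t.hypothesized_sign else "two",
            }
        )
    return pd.DataFrame(rows)


def trace_table(trace: EliminationTrace) -> pd.DataFrame:
    rows = []
    for i, s in enumerate(trace.steps):
        rows.append(
            {
                "step": i + 1,
                "dropped_term": s.dropped_term,
                "p_two_tailed": round(s.p_two_tailed, 6),
                "remaining_terms": ",".join(
                    t for t in s.model_terms if t != s.dropped_term
                ),
            }
        )
    return pd.DataFrame(
        rows, columns=["step", "dropped_term", "p_two_tailed", "remaining_terms"]
    )


def _write_report(
    report: StudyReport, groups: Sequence[GroupData], out_dir: Path
) -> None:
    rep, tr = out_dir / "report", out_dir / "trace"
    rep.mkdir(parents=True, exist_ok=True)
    tr.mkdir(parents=True, exist_ok=True)
    density_table(report.density).to_csv(rep / "density.tsv", sep="\t", index=False)

    manifest: dict = {
        "version": __version__,
        "options": {
            "n_perm": report.options.n_perm,
            "n_boot": report.options.n_boot,
            "alpha": report.options.alpha,
            "seed": report.options.seed,
            "mg_method": report.options.mg_method,
        },
        "groups": {},
        "artifacts": ["report/density.tsv"],
    }
    log_lines = [
        f"dyadqap {__version__}",
        f"seed={report.options.seed} n_perm={report.options.n_perm} "
        f"n_boot={report.options.n_boot} alpha={report.options.alpha}",
    ]
    for g in groups:
        trace = report.group_models[g.group_id]
        name = f"mrqap_{g.group_id}.tsv"
        if trace.final is not None:
            model_table(trace.final).to_csv(rep / name, sep="\t", index=False)
            manifest["artifacts"].append(f"report/{name}")
        trace_table(trace).to_csv(tr / name, sep="\t", index=False)
        dropped = trace.final.n_dropped if trace.final is not None else None
        manifest["groups"][g.group_id] = {
            "n_actors": g.n,
            "final_terms": list(trace.final_terms),
            "n_dropped_dyads": dropped,
        }
        log_lines.append(
            f"group {g.group_id}: n={g.n}, final terms={list(trace.final_terms)}, "
            f"dropped dyads={dropped}"
        )
    if report.mg_model is not None:
        if report.mg_model.final is not None:
            model_table(report.mg_model.final).to_csv(
                rep / "mg_model.tsv", sep="\t", index=False
            )
            manifest["artifacts"].append("report/mg_model.tsv")
        trace_table(report.mg_model).to_csv(tr / "mg_model.tsv", sep="\t", index=False)
        manifest["mg_initial_terms"] = list(report.mg_initial_terms)
        manifest["mg_final_terms"] = list(report.mg_model.final_terms)
        log_lines.append(
            f"multigroup: initial={list(report.mg_initial_terms)} "
            f"final={list(report.mg_model.final_terms)}"
        )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
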