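"""Orchestration: CLI, run configuration, seeding and result tables.

Chains the pipeline on synthetic data — simulate, micro-cost, build
QALYs, within-trial analysis, Markov model, PSA — and writes delimited
result tables mirroring the published layouts (per-arm total costs;
within-trial cost-utility table with CEAC probability columns; the
10-year model scenario table) plus a JSON manifest recording inputs,
seeds and versions so any run can be reproduced byte-for-byte.

All randomness flows from a single root seed split per stage with
``numpy.random.SeedSequence``.  Costs are printed to 0 decimal places,
QALYs to 2, and probabilities as whole percentages (round half-up).
"""

from __future__ import annotations

import json
import shutil
import sys
import time
from dataclasses import asdict, dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import click
import numpy as np
import pandas as pd

from . import __version__
from .cea import CEResult, MISpec, ceac, mi_within_trial, run_within_trial
from .costing import UnitCostTable, costs_frame, total_cost
from .markov import (
    MarkovSpec, PSASpec, SCENARIOS, STRATEGIES, _scenario_spec,
    load_markov_spec, load_psa_spec, psa as run_psa, run_scenarios,
)
from .synthdata import (
    SimConfig, default_config, default_tariff, default_unit_costs,
    simulate_trial, write_patient_tables,
)

__all__ = ["RunConfig", "cli", "render_table1", "render_table3",
           "render_table4", "fmt_cost", "fmt_qaly", "fmt_pct"]

_DATA_DIR = Path(__file__).parent / "data"


def fmt_cost(x: float) -> str:
    return str(Decimal(repr(float(x))).quantize(Decimal("1"), ROUND_HALF_UP))


def fmt_qaly(x: float) -> str:
    return str(Decimal(repr(float(x))).quantize(Decimal("0.01"), ROUND_HALF_UP))


def fmt_pct(p: float) -> str:
    """Probability -> whole percent, round half-up (0.994 -> '99')."""
    return str(Decimal(repr(float(p) * 100.0)).quantize(Decimal("1"), ROUND_HALF_UP))


@dataclass
class RunConfig:
    """Paths, analysis options and sizes for one orchestrated run."""

    out_dir: str = "uroecon_out"
    seed: int = 2025
    n_per_arm: int = 110
    perspective: str = "societal"
    anchor: str = "randomisation"
    rescaled: bool = False
    imputed: bool = False
    bootstrap: int = 1000
    psa_draws: int = 500
    markov_params: str | None = None
    psa_params: str | None = None


def _stage_seeds(root: int) -> dict[str, int]:
    names = ("simulate", "missing", "bootstrap", "impute", "psa")
    children = np.random.SeedSequence(root).spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2**31)) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# table renderers
# ---------------------------------------------------------------------------

def render_table1(records, unit_costs: UnitCostTable) -> pd.DataFrame:
    """Per-arm mean (SD) total cost at each nested perspective."""
    df = costs_frame(records, unit_costs)
    rows = []
    labels = [
        ("Total intervention and re-intervention cost", "intervention_total"),
        ("Total NHS cost (intervention and re-intervention with follow-up)", "nhs_total"),
        ("Total societal cost (NHS and patient costs)", "societal_total"),
    ]
    for label, col in labels:
        row = {"total_cost": label}
        for arm in STRATEGIES:
            sub = df.loc[df["arm_allocated"] == arm, col]
            row[f"{arm}_mean_sd"] = f"{fmt_cost(sub.mean())} ({fmt_cost(sub.std(ddof=1))})"
            row[f"{arm}_n"] = len(sub)
        rows.append(row)
    return pd.DataFrame(rows)


def _ce_rows(name: str, res: CEResult) -> list[dict]:
    fit = res.fit
    thresholds = res.ceac_table["threshold"].tolist()

    def probs(col):
        return {f"p_{int(t/1000)}k": fmt_pct(p)
                for t, p in zip(thresholds, res.ceac_table[col])}

    icer_cell = fmt_cost(res.icer) if res.label == "icer" else (
        "Dominated" if res.label == "dominated" else "Dominant")
    rows = [{
        "analysis": name, "strategy": "urethroplasty",
        "n": res.n_by_arm["urethroplasty"],
        "cost": fmt_cost(fit.adjusted_means["urethroplasty"][0]),
        "incremental_cost":
            f"{fmt_cost(fit.delta_cost)} ({fmt_cost(res.ci_cost[0])}, {fmt_cost(res.ci_cost[1])})",
        "qaly": fmt_qaly(fit.adjusted_means["urethroplasty"][1]),
        "incremental_effect":
            f"{fmt_qaly(fit.delta_qaly)} ({fmt_qaly(res.ci_qaly[0])}, {fmt_qaly(res.ci_qaly[1])})",
        "icer": icer_cell,
        **probs("p_urethroplasty"),
    }, {
        "analysis": name, "strategy": "urethrotomy",
        "n": res.n_by_arm["urethrotomy"],
        "cost": fmt_cost(fit.adjusted_means["urethrotomy"][0]),
        "incremental_cost": "",
        "qaly": fmt_qaly(fit.adjusted_means["urethrotomy"][1]),
        "incremental_effect": "",
        # comparator row carries the dominance verdict, as printed
        "icer": "Dominant" if res.label == "dominated" else "",
        **probs("p_urethrotomy"),
    }]
    return rows


def render_table3(results: dict[str, CEResult]) -> pd.DataFrame:
    """Within-trial cost-utility table, one block per analysis variant."""
    if not results:
        raise ValueError("no within-trial results to render")
    rows = []
    for name, res in results.items():
        if res.ceac_table.empty:
            raise ValueError(f"empty CEAC for analysis {name!r}")
        rows.extend(_ce_rows(name, res))
    return pd.DataFrame(rows)


def render_table4(scenario_df: pd.DataFrame,
                  ceacs: dict[str, pd.DataFrame] | None = None) -> pd.DataFrame:
    """10-year model scenario table with optional PSA probability columns."""
    if scenario_df.empty:
        raise ValueError("no scenario results to render")
    rows = []
    for _, r in scenario_df.iterrows():
        row = {
            "analysis": r["analysis"], "strategy": r["strategy"],
            "cost": fmt_cost(r["cost"]), "qaly": fmt_qaly(r["qaly"]),
            "icer": (fmt_cost(r["icer"]) if r["label"] == "icer"
                     and r["strategy"] == "urethroplasty"
                     else ("Dominant" if r["label"] == "dominated"
                           and r["strategy"] == "urethrotomy" else "")),
        }
        if ceacs and r["analysis"] in ceacs:
            tab = ceacs[r["analysis"]]
            col = f"p_{r['strategy']}"
            for t, p in zip(tab["threshold"], tab[col]):
                row[f"p_{int(t/1000)}k"] = fmt_pct(p)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _write_manifest(out: Path, cfg: RunConfig, seeds: dict[str, int],
                    outputs: list[str]) -> None:
    manifest = {
        "package": "uroecon",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": asdict(cfg),
        "stage_seeds": seeds,
        "outputs": sorted(outputs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _prepare(cfg: RunConfig):
    seeds = _stage_seeds(cfg.seed)
    sim = default_config(n_per_arm=cfg.n_per_arm, seed=seeds["simulate"])
    uc = default_unit_costs()
    tariff = default_tariff()
    records, truth = simulate_trial(sim, uc, tariff)
    return seeds, sim, uc, tariff, records, truth


@click.group()
def cli() -> None:
    """Trial-based cost-utility analysis and 10-year Markov model for
    urethral stricture surgery, run end-to-end on synthetic data."""


def _common(f):
    f = click.option("--out", "out_dir", default="uroecon_out", show_default=True)(f)
    f = click.option("--seed", default=2025, show_default=True, type=int)(f)
    f = click.option("--n", "n_per_arm", default=110, show_default=True, type=int)(f)
    return f


def _run_stage(cfg: RunConfig, stage_fn) -> None:
    out = Path(cfg.out_dir)
    fresh = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    try:
        stage_fn(out, written)
        seeds = _stage_seeds(cfg.seed)
        _write_manifest(out, cfg, seeds, written)
    except Exception as exc:
        for name in written:
            (out / name).unlink(missing_ok=True)
        if fresh and not any(out.iterdir()):
            shutil.rmtree(out, ignore_errors=True)
        raise click.ClickException(str(exc)) from exc


@cli.command()
@_common
def simulate(out_dir, seed, n_per_arm):
    """Generate a synthetic trial dataset (patients + observations)."""
    cfg = RunConfig(out_dir=out_dir, seed=seed, n_per_arm=n_per_arm)

    def stage(out: Path, written: list[str]) -> None:
        _, _, _, _, records, truth = _prepare(cfg)
        write_patient_tables(records, out)
        written += ["patients.csv", "observations.csv"]
        (out / "truth.json").write_text(json.dumps(asdict(truth), indent=2))
        written.append("truth.json")

    _run_stage(cfg, stage)
    click.echo(f"wrote synthetic trial ({2 * n_per_arm} patients) to {out_dir}")


@cli.command()
@_common
def cost(out_dir, seed, n_per_arm):
    """Micro-cost every patient and write per-patient costs + Table 1."""
    cfg = RunConfig(out_dir=out_dir, seed=seed, n_per_arm=n_per_arm)

    def stage(out: Path, written: list[str]) -> None:
        _, _, uc, _, records, _ = _prepare(cfg)
        costs_frame(records, uc).to_csv(out / "costs.csv", index=False)
        render_table1(records, uc).to_csv(out / "table1.csv", index=False)
        written += ["costs.csv", "table1.csv"]

    _run_stage(cfg, stage)
    click.echo(f"wrote costs.csv and table1.csv to {out_dir}")


@cli.command()
@_common
def qaly(out_dir, seed, n_per_arm):
    """Score EQ-5D-5L responses and write per-patient QALYs."""
    from .cea import build_analysis_frame

    cfg = RunConfig(out_dir=out_dir, seed=seed, n_per_arm=n_per_arm)

    def stage(out: Path, written: list[str]) -> None:
        _, _, uc, tariff, records, _ = _prepare(cfg)
        frames = []
        for anchor in ("randomisation", "surgery"):
            for rescaled in (False, True):
                f = build_analysis_frame(records, uc, tariff, anchor=anchor,
                                         rescaled=rescaled)
                f["anchor"] = anchor
                f["rescaled"] = rescaled
                frames.append(f[["id", "anchor", "rescaled", "qaly", "complete"]])
        pd.concat(frames).to_csv(out / "qalys.csv", index=False)
        written.append("qalys.csv")

    _run_stage(cfg, stage)
    click.echo(f"wrote qalys.csv to {out_dir}")


@cli.command()
@_common
@click.option("--perspective", default="societal", show_default=True,
              type=click.Choice(["intervention", "nhs", "societal"]))
@click.option("--qaly-variant", "variant", default="randomisation", show_default=True,
              help="anchor[,rescaled][,imputed], e.g. surgery,rescaled")
@click.option("--bootstrap", "-B", default=1000, show_default=True, type=int)
def cea(out_dir, seed, n_per_arm, perspective, variant, bootstrap):
    """Within-trial cost-utility analysis with bootstrap CEAC."""
    parts = [p.strip() for p in variant.split(",")]
    anchor = parts[0]
    rescaled = "rescaled" in parts[1:]
    imputed = "imputed" in parts[1:]
    cfg = RunConfig(out_dir=out_dir, seed=seed, n_per_arm=n_per_arm,
                    perspective=perspective, anchor=anchor, rescaled=rescaled,
                    imputed=imputed, bootstrap=bootstrap)

    def stage(out: Path, written: list[str]) -> None:
        seeds, _, uc, tariff, records, _ = _prepare(cfg)
        res = run_within_trial(records, uc, tariff, perspective=perspective,
                               anchor=anchor, rescaled=rescaled,
                               B=bootstrap, seed=seeds["bootstrap"])
        name = anchor + (",rescaled" if rescaled else "")
        render_table3({name: res}).to_csv(out / "table3.csv", index=False)
        res.ceac_table.to_csv(out / "ceac_points.csv", index=False)
        pd.DataFrame(res.draws, columns=["delta_cost", "delta_qaly"]) \
            .to_csv(out / "ce_plane_draws.csv", index=False)
        written += ["table3.csv", "ceac_points.csv", "ce_plane_draws.csv"]
        if imputed:
            mi = mi_within_trial(records, uc, tariff,
                                 MISpec(m=25, seed=seeds["impute"]),
                                 perspective=perspective, anchor=anchor,
                                 rescaled=rescaled)
            (out / "mi_result.json").write_text(json.dumps(mi, indent=2))
            written.append("mi_result.json")

    _run_stage(cfg, stage)
    click.echo(f"wrote within-trial CEA outputs to {out_dir}")


@cli.command()
@_common
@click.option("--params", "markov_params", default=None,
              help="markov_params.yaml (default: shipped file)")
def markov(out_dir, seed, n_per_arm, markov_params):
    """Run the 10-year Markov model scenarios (Table 4 layout)."""
    cfg = RunConfig(out_dir=out_dir, seed=seed, markov_params=markov_params)

    def stage(out: Path, written: list[str]) -> None:
        spec = load_markov_spec(markov_params or _DATA_DIR / "markov_params.yaml")
        df = run_scenarios(spec)
        df.drop(columns=["label"]).to_csv(out / "markov_scenarios.csv", index=False)
        render_table4(df).to_csv(out / "table4.csv", index=False)
        written += ["markov_scenarios.csv", "table4.csv"]

    _run_stage(cfg, stage)
    click.echo(f"wrote table4.csv to {out_dir}")


@cli.command("psa")
@_common
@click.option("--params", "markov_params", default=None)
@click.option("--psa-params", default=None)
@click.option("--psa-draws", "-N", default=500, show_default=True, type=int)
def psa_cmd(out_dir, seed, n_per_arm, markov_params, psa_params, psa_draws):
    """Probabilistic sensitivity analysis of the Markov model."""
    cfg = RunConfig(out_dir=out_dir, seed=seed, markov_params=markov_params,
                    psa_params=psa_params, psa_draws=psa_draws)

    def stage(out: Path, written: list[str]) -> None:
        seeds = _stage_seeds(cfg.seed)
        spec = load_markov_spec(markov_params or _DATA_DIR / "markov_params.yaml")
        pspec = load_psa_spec(psa_params or _DATA_DIR / "psa.yaml")
        pspec.n_draws = psa_draws
        pspec.seed = seeds["psa"]
        res = run_psa(spec, pspec)
        pd.DataFrame(res["deltas"], columns=["delta_cost", "delta_qaly"]) \
            .to_csv(out / "psa_draws.csv", index=False)
        res["ceac"].to_csv(out / "ceac_model.csv", index=False)
        written += ["psa_draws.csv", "ceac_model.csv"]

    _run_stage(cfg, stage)
    click.echo(f"wrote PSA outputs to {out_dir}")


@cli.command("all")
@_common
@click.option("--perspective", default="societal", show_default=True,
              type=click.Choice(["intervention", "nhs", "societal"]))
@click.option("--bootstrap", "-B", default=1000, show_default=True, type=int)
@click.option("--psa-draws", "-N", default=500, show_default=True, type=int)
def run_all(out_dir, seed, n_per_arm, perspective, bootstrap, psa_draws):
    """Chain the full pipeline on synthetic data."""
    cfg = RunConfig(out_dir=out_dir, seed=seed, n_per_arm=n_per_arm,
                    perspective=perspective, bootstrap=bootstrap,
                    psa_draws=psa_draws)

    def stage(out: Path, written: list[str]) -> None:
        seeds, _, uc, tariff, records, truth = _prepare(cfg)
        write_patient_tables(records, out)
        (out / "truth.json").write_text(json.dumps(asdict(truth), indent=2))
        costs_frame(records, uc).to_csv(out / "costs.csv", index=False)
        render_table1(records, uc).to_csv(out / "table1.csv", index=False)
        written += ["patients.csv", "observations.csv", "truth.json",
                    "costs.csv", "table1.csv"]
        results = {}
        for i, (anchor, rescaled) in enumerate(
                [("randomisation", False), ("randomisation", True),
                 ("surgery", False), ("surgery", True)]):
            name = anchor + (",rescaled" if rescaled else "")
            results[name] = run_within_trial(
                records, uc, tariff, perspective=perspective, anchor=anchor,
                rescaled=rescaled, B=bootstrap, seed=seeds["bootstrap"] + i)
        render_table3(results).to_csv(out / "table3.csv", index=False)
        base = results["randomisation"]
        base.ceac_table.to_csv(out / "ceac_points.csv", index=False)
        pd.DataFrame(base.draws, columns=["delta_cost", "delta_qaly"]) \
            .to_csv(out / "ce_plane_draws.csv", index=False)
        written += ["table3.csv", "ceac_points.csv", "ce_plane_draws.csv"]
        spec = load_markov_spec(_DATA_DIR / "markov_params.yaml")
        scen = run_scenarios(spec)
        pspec = load_psa_spec(_DATA_DIR / "psa.yaml")
        pspec.n_draws = psa_draws
        ceacs = {}
        for i, sc in enumerate(SCENARIOS):
            p = PSASpec(params=pspec.params, n_draws=psa_draws,
                        seed=seeds["psa"] + i)
            ceacs[sc] = run_psa(_scenario_spec(spec, sc), p)["ceac"]
        render_table4(scen, ceacs).to_csv(out / "table4.csv", index=False)
        ceacs["base_case"].to_csv(out / "ceac_model.csv", index=False)
        written += ["table4.csv", "ceac_model.csv"]

    _run_stage(cfg, stage)
    click.echo(f"full pipeline outputs written to {out_dir}")


if __name__ == "__main__":  # pragma: no cover
    cli()
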