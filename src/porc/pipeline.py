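"""End-to-end orchestration: simulate -> QC -> derive/classify -> evaluate -> risk.

Produces a reproducible report bundle (cohort CSV, exclusion ledger JSON,
grown-tree JSON, evaluation JSON with a text table mirroring the familiar
tool x cut-off layout, and risk CSVs) plus a manifest recording the seed,
a configuration hash and a checksum of every artefact, so a rerun from the
same configuration reproduces the bundle bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import algorithm, cart, diagnostics, qc, risk, simulate
from .cohort import PatientRecord, write_cohort_csv
from .errors import ConfigError

log = logging.getLogger("porc")


@dataclass
class RunConfig:
    """Parameters of a full pipeline run."""

    seed: int = 0
    outdir: Path = Path("porc_run")
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    cart: cart.CartConfig = field(default_factory=cart.CartConfig)
    tree_path: Optional[Path] = None  # None -> published pathway
    epsilons: tuple[float, ...] = (0.7, 0.9)
    risk_grid_points: int = 101
    log_level: str = "INFO"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = simulate.SimulationConfig.from_dict(data.get("simulation", {}))
        cart_cfg = cart.CartConfig(**data.get("cart", {}))
        cart_cfg.validate()
        try:
            return cls(
                seed=int(data.get("seed", 0)),
                outdir=Path(data.get("outdir", "porc_run")),
                simulation=sim,
                cart=cart_cfg,
                tree_path=Path(data["tree_path"]) if data.get("tree_path") else None,
                epsilons=tuple(data.get("epsilons", (0.7, 0.9))),
                risk_grid_points=int(data.get("risk_grid_points", 101)),
                log_level=str(data.get("log_level", "INFO")),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    def canonical_dict(self) -> dict:
        return {
            "seed": self.seed,
            "simulation": self.simulation.to_dict(),
            "cart": dataclasses.asdict(self.cart),
            "tree_path": str(self.tree_path) if self.tree_path else None,
            "epsilons": list(self.epsilons),
            "risk_grid_points": self.risk_grid_points,
        }


# ---------------------------------------------------------------------------
# Table rendering


def _fmt_pct(value: float) -> str:
    """Percent formatting of the published table: one decimal, bare 100."""
    pct = value * 100.0
    if pct == 100.0:
        return "100"
    return f"{pct:.1f}"


def format_accuracy_cell(acc: diagnostics.DiagnosticAccuracy, which: str) -> str:
    """Render one sens/spec cell as ``point% [lower; upper]``."""
    if which == "sens":
        point, (lo, hi) = acc.sens, acc.sens_ci
    elif which == "spec":
        point, (lo, hi) = acc.spec, acc.spec_ci
    else:
        raise ValueError("which must be 'sens' or 'spec'")
    return f"{_fmt_pct(point)}% [{_fmt_pct(lo)}; {_fmt_pct(hi)}]"


def render_table3(
    evaluations: dict[str, dict[float, diagnostics.DiagnosticAccuracy]],
) -> tuple[str, dict]:
    """Tool x cut-off accuracy grid, as text and as a JSON-ready dict.

    ``evaluations`` maps tool name -> {epsilon -> DiagnosticAccuracy}.
    Tools with no evaluations are omitted with a warning.  Each tool
    carries its own n (per-tool missingness is possible in practice).
    """
    tools = []
    for tool, by_eps in evaluations.items():
        if not by_eps:
            log.warning("tool %r has no evaluations; column omitted", tool)
            continue
        tools.append(tool)
    if not tools:
        raise ValueError("no evaluations to render")
    epsilons = sorted({e for t in tools for e in evaluations[t]}, reverse=True)
    width = max(28, max(len(t) for t in tools) + 2)
    lines = ["".ljust(24) + "".join(t.ljust(width) for t in tools)]
    payload: dict = {}
    for eps in epsilons:
        lines.append(f"TOF < {eps:g}")
        for which, label in (("sens", "Sensitivity"), ("spec", "Specificity")):
            row = [("  " + label).ljust(24)]
            for tool in tools:
                acc = evaluations[tool].get(eps)
                cell = format_accuracy_cell(acc, which) if acc else "-"
                row.append(cell.ljust(width))
                if acc:
                    payload.setdefault(tool, {}).setdefault(
                        f"tof_lt_{eps:g}", {}
                    )[which] = {
                        "point": getattr(acc, which),
                        "ci": list(getattr(acc, f"{which}_ci")),
                        "n": acc.table.n_diseased if which == "sens"
                        else acc.table.n_healthy,
                    }
            lines.append("".join(row).rstrip())
    return "\n".join(lines) + "\n", payload


# ---------------------------------------------------------------------------
# Tool predictions on a cohort


def tool_predictions(
    records: Sequence[PatientRecord],
    spec: algorithm.DecisionTreeSpec,
    epsilon: float,
) -> dict[str, list[bool]]:
    """Block predictions of the three tools for every analysable patient."""
    algo: list[bool] = []
    for rec in records:
        res = algorithm.classify(rec.scores, spec)
        if not res.classified:
            raise ConfigError(
                f"patient {rec.id} unclassifiable (missing {res.missing}); "
                "apply exclusions before evaluation"
            )
        flag = (res.predicted_block_lt_07 if epsilon <= 0.7
                else res.predicted_block_lt_09)
        algo.append(bool(flag))
    amg = [rec.amg_tofr < epsilon for rec in records]
    tactile = [
        diagnostics.dichotomize_tactile(rec.tactile_fading) == diagnostics.BLOCK
        for rec in records
    ]
    return {"algorithm": algo, "amg": amg, "tactile": tactile}


def evaluate_cohort(
    records: Sequence[PatientRecord],
    spec: algorithm.DecisionTreeSpec,
    epsilons: Sequence[float] = (0.7, 0.9),
    confidence: float = 0.95,
) -> dict[str, dict[float, diagnostics.DiagnosticAccuracy]]:
    emg = [rec.emg_tofr for rec in records]
    out: dict[str, dict[float, diagnostics.DiagnosticAccuracy]] = {}
    for eps in epsilons:
        preds = tool_predictions(records, spec, eps)
        for tool, pred in preds.items():
            out.setdefault(tool, {})[eps] = diagnostics.evaluate_tool(
                pred, emg, eps, confidence=confidence
            )
    return out


# ---------------------------------------------------------------------------
# Full pipeline


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and write the report bundle.

    Returns the manifest (also written to ``manifest.json``): seed, config
    hash and per-file checksums.  Any stage failure aborts with a
    stage-named error.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}

    def stage(name: str):
        log.info("stage: %s", name)

    try:
        stage("simulate")
        sim_cfg = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate.simulate_cohort(sim_cfg)
        files["cohort.csv"] = out / "cohort.csv"
        files["traces.csv"] = out / "traces.csv"
        write_cohort_csv(cohort, files["cohort.csv"], files["traces.csv"])
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("qc")
        analysable, ledger = qc.apply_exclusions(cohort)
        files["ledger.json"] = out / "ledger.json"
        ledger.to_json(files["ledger.json"])
        files["analysable.csv"] = out / "analysable.csv"
        write_cohort_csv(analysable, files["analysable.csv"])
    except Exception as exc:
        raise RuntimeError(f"stage 'qc' failed: {exc}") from exc

    try:
        stage("fit-cart")
        X = pd.DataFrame([r.scores.as_dict() for r in analysable])
        y = np.array([r.emg_tofr for r in analysable])
        tree = cart.grow(X, y, config.cart)
        files["tree.json"] = out / "tree.json"
        tree.save_spec(files["tree.json"])
    except Exception as exc:
        raise RuntimeError(f"stage 'fit-cart' failed: {exc}") from exc

    try:
        stage("evaluate")
        spec = (algorithm.DecisionTreeSpec.from_json(config.tree_path)
                if config.tree_path else algorithm.default_published_tree())
        evals = evaluate_cohort(analysable, spec, config.epsilons)
        text, payload = render_table3(evals)
        files["evaluation.json"] = out / "evaluation.json"
        files["evaluation.json"].write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )
        files["table3.txt"] = out / "table3.txt"
        files["table3.txt"].write_text(text)
    except Exception as exc:
        raise RuntimeError(f"stage 'evaluate' failed: {exc}") from exc

    try:
        stage("risk")
        grid = np.linspace(0.0, 1.0, config.risk_grid_points)
        rows = []
        for tool, by_eps in evals.items():
            for eps, acc in by_eps.items():
                curve = risk.risk_curve(
                    acc.sens, acc.spec, grid, acc.sens_ci, acc.spec_ci
                )
                for i, p in enumerate(curve.prevalence):
                    rows.append({
                        "tool": tool, "epsilon": eps, "prevalence": p,
                        "risk": curve.risk[i],
                        "lower": curve.lower[i], "upper": curve.upper[i],
                    })
        files["risk.csv"] = out / "risk.csv"
        pd.DataFrame(rows).to_csv(files["risk.csv"], index=False)
    except Exception as exc:
        raise RuntimeError(f"stage 'risk' failed: {exc}") from exc

    stage("manifest")
    cfg_json = json.dumps(config.canonical_dict(), sort_keys=True)
    manifest = {
        "seed": config.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": {name: _sha256(path) for name, path in sorted(files.items())},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
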