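"""End-to-end orchestration: inputs -> filter -> map -> concordance.

A run is described by a YAML config naming either a simulation preset or
a list of per-screen input tables.  Every stage logs its record tallies
— the analysis' headline numbers are all stage tallies, so they are
first-class outputs — and the run ends with a machine-readable summary.
Reruns with identical config and inputs are deterministic.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from concord import homology as hom
from concord import io as cio
from concord import reanalysis as rean
from concord import simulate as sim
from concord.concordance import build_matrix, select_candidates, tier_counts

log = logging.getLogger("concord")


class ConfigError(ValueError):
    """The run config fails schema validation (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name (CLI exit code 3)."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunSummary:
    """Machine-readable account of one pipeline run."""

    seed: int | None
    config: dict
    per_screen: dict[str, dict[str, int]] = field(default_factory=dict)
    mapping: dict[str, dict[str, int]] = field(default_factory=dict)
    tier_counts: dict[str, Any] = field(default_factory=dict)
    n_candidates: int | None = None
    recovery: dict[str, Any] | None = None
    outputs: dict[str, str] = field(default_factory=dict)

    def validate(self) -> None:
        for sid, counts in self.per_screen.items():
            if counts["kept"] != counts["up"] + counts["down"]:
                raise AssertionError(f"{sid}: kept != up + down")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    config = yaml.safe_load(path.read_text())
    if not isinstance(config, dict):
        raise ConfigError("config must be a YAML mapping")
    if ("simulate" in config) == ("screens" in config):
        raise ConfigError("config needs exactly one of 'simulate' or 'screens'")
    return config


def _simulate_stage(config: dict, out_dir: Path):
    params = dict(config["simulate"])
    preset = params.pop("preset", None)
    if preset is not None:
        if preset != "recovery":
            raise ConfigError(f"unknown preset {preset!r}")
        merged = dict(sim.RECOVERY_PRESET)
        merged.update(params)
        params = merged
    params.setdefault("seed", config.get("seed", 0))
    try:
        screens, homology, truth = sim.gen_multiscreen(**params)
    except TypeError as exc:
        raise ConfigError(f"bad simulate parameters: {exc}") from None
    for s in screens:
        cio.write_expression_matrix(s.matrix, out_dir / f"{s.screen_id}_expression.tsv")
    homology.groups.to_csv(out_dir / "homology.tsv", sep="\t", index=False)
    _write_truth(truth, out_dir / "truth.tsv")
    return screens, homology, truth


def _write_truth(truth: sim.SimTruth, path: Path) -> None:
    rows = []
    for kind, store in (
        ("concordant", truth.planted_concordant),
        ("discordant", truth.planted_discordant),
    ):
        for gene, per_screen in store.items():
            for sid, eff in per_screen.items():
                rows.append({"gene": gene, "kind": kind, "screen": sid, "effect": eff})
    pd.DataFrame(rows, columns=["gene", "kind", "screen", "effect"]).to_csv(
        path, sep="\t", index=False
    )


def _read_screens(config: dict):
    results = []
    matrices = []
    for spec in config["screens"]:
        for key in ("id", "species", "path"):
            if key not in spec:
                raise ConfigError(f"screen entry missing {key!r}: {spec}")
        path = Path(spec["path"])
        if not path.exists():
            raise StageError("read", f"screen file not found: {path}")
        kind = spec.get("kind", "de_table")
        if kind == "expression":
            matrix = cio.read_expression_matrix(path, spec["group_map"])
            matrices.append((spec["id"], spec["species"], matrix))
        elif kind == "de_table":
            results.append(
                cio.read_de_table(
                    path,
                    screen_id=spec["id"],
                    species=spec["species"],
                    dialect=spec.get("dialect", "generic"),
                    fc_scale=spec.get("fc_scale", "log2"),
                )
            )
        else:
            raise ConfigError(f"unknown screen kind {kind!r}")
    return results, matrices


def run_pipeline(config_path: str | Path) -> RunSummary:
    """Run the full analysis described by a YAML config; see docs."""
    config = _load_config(config_path)
    out_dir = Path(config.get("out_dir", "concord_out"))
    out_dir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(seed=config.get("seed"), config=config)

    truth = None
    homology = None
    de_results: list = []
    matrices: list = []

    if "simulate" in config:
        screens, homology, truth = _simulate_stage(config, out_dir)
        matrices = [(s.screen_id, s.species, s.matrix) for s in screens]
    else:
        de_results, matrices = _read_screens(config)
        if config.get("homology"):
            hpath = Path(config["homology"])
            if not hpath.exists():
                raise StageError("homology", f"homology table not found: {hpath}")
            homology = hom.read_homology_table(hpath)

    # expression matrices -> normalise -> per-gene test; the moderated
    # variance test is the default at these replicate counts
    de_method = config.get("de_method", "moderated")
    for sid, species, matrix in matrices:
        try:
            normalised = rean.quantile_normalize(matrix)
            de_results.append(
                rean.de_test(
                    normalised, screen_id=sid, species=species, method=de_method
                )
            )
        except ValueError as exc:
            raise StageError("de_test", f"{sid}: {exc}") from exc
    log.info("screens ready: %s", [r.screen_id for r in de_results])

    # significance / fold-change filter
    fparams = rean.DeFilterParams(**config.get("filter", {}))
    filtered = []
    for result in de_results:
        if config.get("prefiltered"):
            fs = rean.FilteredScreen(
                screen=result,
                n_kept=len(result),
                n_up=int((result.records["log2fc"] > 0).sum()),
                n_down=int((result.records["log2fc"] < 0).sum()),
            )
        else:
            fs = rean.filter_de(result, fparams)
        summary.per_screen[result.screen_id] = {
            "input": len(result), "kept": fs.n_kept, "up": fs.n_up, "down": fs.n_down,
        }
        log.info(
            "%s: kept %d (%d up / %d down) of %d",
            result.screen_id, fs.n_kept, fs.n_up, fs.n_down, len(result),
        )
        filtered.append(fs.screen)

    # harmonise to the mouse namespace
    mapped = []
    for screen in filtered:
        if homology is None:
            mapped.append(screen)
            continue
        try:
            ms = hom.map_to_reference(screen, homology)
        except ValueError as exc:
            raise StageError("homology", f"{screen.screen_id}: {exc}") from exc
        summary.mapping[screen.screen_id] = {
            "unmapped": ms.n_unmapped,
            "collapsed": ms.n_collapsed,
            "conflicted": ms.n_conflicted,
            "emitted": ms.n_emitted,
        }
        mapped.append(ms.screen)

    # concordance matrix and tiers
    try:
        matrix = build_matrix(mapped)
    except ValueError as exc:
        raise StageError("concordance", str(exc)) from exc
    tiers = tier_counts(matrix)
    summary.tier_counts = {
        "exact": {int(k): int(v) for k, v in tiers.exact["total"].items()},
        "at_least": {int(k): int(v) for k, v in tiers.at_least["total"].items()},
        "exact_up": {int(k): int(v) for k, v in tiers.exact["up"].items()},
        "exact_down": {int(k): int(v) for k, v in tiers.exact["down"].items()},
        "discordant": tiers.n_discordant,
    }

    matrix_path = out_dir / "concordance.tsv"
    if len(matrix.ref_symbols):
        cio.write_concordance_table(matrix, matrix_path)
        summary.outputs["concordance"] = str(matrix_path)

    # candidate selection (optional)
    if "candidates" in config:
        cconf = dict(config["candidates"])
        annotations: dict[str, set[str]] = {}
        if cconf.get("annotations"):
            ann = pd.read_csv(cconf["annotations"], sep="\t")
            for row in ann.itertuples(index=False):
                annotations.setdefault(str(row.symbol), set()).add(str(row.cluster))
        cands = select_candidates(
            matrix,
            cluster_annotations=annotations,
            clusters_wanted=set(cconf.get("clusters", [])),
            min_tier=int(cconf.get("min_tier", 3)),
        )
        cands.to_csv(out_dir / "candidates.tsv", sep="\t", index=False)
        summary.n_candidates = len(cands)
        summary.outputs["candidates"] = str(out_dir / "candidates.tsv")

    if truth is not None:
        report = sim.evaluate_recovery(matrix, truth)
        summary.recovery = {
            "sensitivity": {
                int(k): float(v) for k, v in report.per_tier["sensitivity"].items()
            },
            "precision": {
                int(k): (None if pd.isna(v) else float(v))
                for k, v in report.per_tier["precision"].items()
            },
            "n_discordant_called": report.n_discordant_called,
        }

    summary.validate()
    summary.to_json(out_dir / "run_summary.json")
    summary.outputs["summary"] = str(out_dir / "run_summary.json")
    return summary
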