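"""End-to-end orchestration: structure -> (simulated) ensemble -> statistics.

``run_full_analysis`` executes the configured stages, writes every output
table as plain delimited text or JSON, and records a manifest (config hash,
row counts, stage timings) so a rerun with the same configuration
reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .ensemble_stats import (MutantEnsemble, hbc_by_pair_grid,
                             helix_group_comparison,
                             normalized_size_outlier_rates, outliers,
                             pair_frequency_matrix, position_frequency,
                             residue_frequency, top_pairs)
from .interactions import InteractionConfig
from .metrics import metric_record
from .structure_model import (ProteinStructure, read_pdb, structure_summary,
                              write_pdb)
from .synthetic_data import (PlantedEffect, SyntheticEnsembleConfig,
                             ideal_helix_structure, simulate_metric_ensemble)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Full configuration for one analysis run (serialized with outputs)."""
    out_dir: str = "insertscan_out"
    pdb_path: str | None = None          # wildtype structure
    ensemble_csv: str | None = None      # precomputed metric table, optional
    simulate_n: int | None = None        # simulate over an n-residue helix fixture
    helix_ranges: list[tuple[int, int]] = field(default_factory=list)
    metrics: tuple[str, ...] = ("hbc", "cce", "rop")
    k: float = 2.0
    seed: int = 0
    coverage: float = 1.0
    planted: list[tuple[str, str, str, float]] = field(default_factory=list)
    # (column, value, metric, shift_sd)
    interaction_config: InteractionConfig = field(default_factory=InteractionConfig)
    welch: bool = False
    rate_denominator: str = "group"
    top_k: int = 30


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_structure(config: RunConfig) -> ProteinStructure:
    if config.pdb_path:
        return read_pdb(config.pdb_path)
    if config.simulate_n:
        # synthetic scaffold: ideal helix geometry with the requested length,
        # re-annotated with the configured helix ranges
        st = ideal_helix_structure(config.simulate_n)
        st.helix_ranges = [tuple(r) for r in config.helix_ranges]
        st.__post_init__()
        return st
    raise ValueError("config needs pdb_path or simulate_n")


def run_full_analysis(config: RunConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": dataclasses.asdict(config),
                      "config_hash": _config_hash(config),
                      "version": __version__,
                      "stages": {}}
    written: list[Path] = []
    try:
        t0 = time.perf_counter()
        structure = _load_structure(config)
        summary = structure_summary(structure)
        _write_json(out / "structure.json", summary, written)
        manifest["stages"]["structure"] = {
            "n_residues": summary["n_residues"],
            "seconds": round(time.perf_counter() - t0, 3)}

        t0 = time.perf_counter()
        if config.ensemble_csv:
            ensemble = MutantEnsemble.from_csv(config.ensemble_csv)
        else:
            sim = SyntheticEnsembleConfig(
                planted_effects=[PlantedEffect((col, val), metric, shift)
                                 for col, val, metric, shift in config.planted],
                seed=config.seed, coverage=config.coverage)
            ensemble = simulate_metric_ensemble(sim, structure)
        ensemble.to_csv(out / "ensemble.csv")
        written.append(out / "ensemble.csv")
        manifest["stages"]["ensemble"] = {
            "rows": len(ensemble),
            "seconds": round(time.perf_counter() - t0, 3)}

        t0 = time.perf_counter()
        stats_info = run_stats_suite(ensemble, structure, out, config, written)
        manifest["stages"]["stats"] = {
            **stats_info, "seconds": round(time.perf_counter() - t0, 3)}
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        stage = len(manifest["stages"])
        names = ["structure", "ensemble", "stats"]
        failed = names[min(stage, 2)]
        raise RuntimeError(f"stage {failed!r} failed: {exc}") from exc

    _write_json(out / "manifest.json", manifest, written)
    logger.info("run complete: %d files in %s", len(written), out)
    return manifest


def run_stats_suite(ensemble: MutantEnsemble, structure: ProteinStructure,
                    out: Path, config: RunConfig,
                    written: list[Path] | None = None) -> dict:
    """Write the full statistics table set for each configured metric."""
    written = written if written is not None else []
    info: dict = {}
    for metric in config.metrics:
        oset = outliers(ensemble, metric, config.k)
        prefix = out / metric
        prefix.mkdir(exist_ok=True)
        ids = sorted(oset.member_ids)
        pd.DataFrame({"mutant_id": ids}).to_csv(prefix / "outliers.csv", index=False)
        rf = residue_frequency(ensemble, oset)
        pd.Series(rf, name="count").rename_axis("aa").to_csv(prefix / "residue_freq.csv")
        pair_frequency_matrix(ensemble, oset).to_csv(prefix / "pair_matrix.csv")
        position_frequency(ensemble, oset, structure).to_csv(
            prefix / "position_freq.csv", index=False)

        rows = ensemble.records
        orows = rows[rows["mutant_id"].isin(oset.member_ids)]
        pair_counts: dict[tuple, int] = {}
        for a1_, a2_ in zip(orows["aa1"], orows["aa2"]):
            key = tuple(sorted((a1_, a2_)))
            pair_counts[key] = pair_counts.get(key, 0) + 1
        if pair_counts:
            pairs, top5 = top_pairs(pair_counts, config.top_k)
            _write_json(prefix / "top_pairs.json",
                        {"pairs": ["".join(p) for p in pairs],
                         "top_elements": top5}, written)

        comparisons = helix_group_comparison(ensemble, metric)
        _write_json(prefix / "helix_groups.json",
                    {name: {"d": c["effect"].d, "t": c["effect"].t,
                            "p": c["effect"].p,
                            "n1": c["effect"].n1, "n2": c["effect"].n2}
                     for name, c in comparisons.items()}, written)
        normalized_size_outlier_rates(
            ensemble, metric, config.k,
            denominator=config.rate_denominator).to_csv(
                prefix / "size_rates.csv", index=False)
        info[metric] = {"outliers": len(oset),
                        "outlier_fraction": len(oset) / len(ensemble)}
        written.extend(prefix / f for f in
                       ("outliers.csv", "residue_freq.csv", "pair_matrix.csv",
                        "position_freq.csv", "size_rates.csv"))
    if "hbc" in config.metrics:
        hbc_by_pair_grid(ensemble).to_csv(out / "hbc_grid.csv")
        written.append(out / "hbc_grid.csv")
    return info


def metrics_table(structures: list[ProteinStructure],
                  config: InteractionConfig | None = None) -> pd.DataFrame:
    """Run the metric pipeline over real structures into a tidy table."""
    records = [metric_record(s, config=config or InteractionConfig())
               for s in structures]
    return pd.DataFrame([dataclasses.asdict(r) for r in records])


def _write_json(path: Path, obj, written: list[Path]) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=str)
    written.append(path)
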