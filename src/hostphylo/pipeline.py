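"""Config-driven end-to-end orchestration.

A run takes either real inputs (fly tree, host tree, association table) or a
named simulation preset, and executes the stages breadth -> phylogenetic
signal -> host-sharing regression -> chronogram -> DEC* reconstruction,
writing machine-readable artifacts plus a MANIFEST marking stage
completeness. Every random draw descends from a single master seed through
named per-stage substreams, so stages can be re-run independently yet
reproducibly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import associations as assoc
from . import dec as decmod
from . import host_sharing, phylosignal, synthetic
from .trees import (
    PhyloTree,
    check_ultrametric,
    patristic_distances,
    strict_clock_chronogram,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage child seed derived from the master seed."""
    h = hashlib.blake2b(f"{master}:{stage}".encode(), digest_size=4).digest()
    return int.from_bytes(h, "big") % (2**31 - 1)


@dataclass
class RunConfig:
    outdir: str = "hostphylo_run"
    seed: int = 0
    # inputs: either paths or a simulation preset
    fly_tree: str | None = None
    host_tree: str | None = None
    associations: str | None = None
    simulate_preset: str | None = None  # "dacini-like" or "small"
    # stage parameters
    polyphagy_thresholds: tuple[int, ...] = (2, 3, 4)
    n_perm: int = 10_000
    n_runs: int = 1000
    min_hosts: int = 3
    k_main_families: int = 9
    max_range_size: int | None = None
    dec_max_families: int = 20
    dec_exclude: tuple[str, ...] = ()
    root_age: float = 1.0
    stages: tuple[str, ...] = ("breadth", "signal", "sharing", "chronogram", "dec")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("polyphagy_thresholds", "dec_exclude", "stages"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


PRESETS = {
    # marginal counts of the curated study system
    "dacini-like": dict(
        n_flies=37,
        n_genera=286,
        n_families=87,
        breadth_profile={
            "n_monophages": 8,
            "n_extreme_polyphages": 11,
            "extreme_min_families": 20,
        },
    ),
    "small": dict(n_flies=12, n_genera=40, n_families=10, breadth_profile=None),
}


def _setup_logging(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    logging.getLogger("hostphylo").addHandler(handler)
    logging.getLogger("hostphylo").setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; return the MANIFEST dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(outdir)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "complete": False,
    }

    def save_manifest() -> None:
        with open(outdir / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    try:
        config.to_yaml(outdir / "config.yaml")
        table, fly_tree, host_tree = _load_inputs(config, outdir, manifest)
        _validate_stage_inputs(config, table, fly_tree, host_tree)

        if "breadth" in config.stages:
            profile = assoc.host_breadth(table)
            profile.to_csv(outdir / "breadth.tsv", sep="\t")
            manifest["stages"]["breadth"] = {"files": ["breadth.tsv"]}
            save_manifest()
        else:
            profile = assoc.host_breadth(table)

        if "signal" in config.stages:
            _stage_signal(config, table, fly_tree, profile, outdir)
            manifest["stages"]["signal"] = {"files": ["signal_table.tsv"]}
            save_manifest()

        if "sharing" in config.stages:
            _stage_sharing(config, table, host_tree, outdir)
            manifest["stages"]["sharing"] = {
                "files": ["sharing_runs.tsv", "sharing_summary.json", "sharing_curve.tsv"]
            }
            save_manifest()

        chronogram = None
        if "chronogram" in config.stages or "dec" in config.stages:
            ok, _ = check_ultrametric(fly_tree, rel_tol=1e-8)
            chronogram = (
                fly_tree
                if ok
                else strict_clock_chronogram(fly_tree, root_age=config.root_age)
            )
            if not ok:
                logger.info("fly tree rescaled to a strict-clock chronogram")
            chronogram.write(outdir / "chronogram.nwk")
            if "chronogram" in config.stages:
                manifest["stages"]["chronogram"] = {"files": ["chronogram.nwk"]}
                save_manifest()

        if "dec" in config.stages:
            _stage_dec(config, table, chronogram, outdir)
            manifest["stages"]["dec"] = {
                "files": ["dec_params.json", "dec_node_states.tsv", "dec_annotated.nwk"]
            }
            save_manifest()

        manifest["complete"] = all(s in manifest["stages"] for s in config.stages)
        save_manifest()
        return manifest
    except Exception as exc:
        failed = [s for s in config.stages if s not in manifest["stages"]]
        stage = failed[0] if failed else "setup"
        manifest["error"] = f"stage '{stage}' failed: {exc}"
        save_manifest()
        raise RuntimeError(manifest["error"]) from exc
    finally:
        logging.getLogger("hostphylo").removeHandler(handler)
        handler.close()


def _validate_stage_inputs(config, table, fly_tree, host_tree) -> None:
    """Pre-flight check: every enabled stage has the inputs it needs."""
    need = {
        "breadth": [table],
        "signal": [table, fly_tree],
        "sharing": [table, host_tree],
        "chronogram": [fly_tree],
        "dec": [table, fly_tree],
    }
    for stage in config.stages:
        if stage not in need:
            raise ValueError(f"unknown stage {stage!r}")
        if any(x is None for x in need[stage]):
            raise ValueError(f"stage {stage!r} enabled but its inputs are missing")


def _load_inputs(config: RunConfig, outdir: Path, manifest: dict):
    if config.simulate_preset:
        if config.simulate_preset not in PRESETS:
            raise ValueError(
                f"unknown preset {config.simulate_preset!r}; "
                f"choose from {sorted(PRESETS)}"
            )
        kwargs = PRESETS[config.simulate_preset]
        system = synthetic.simulate_association_system(
            seed=stage_seed(config.seed, "simulate"), **kwargs
        )
        system.table.write(outdir / "associations.tsv")
        system.fly_tree.write(outdir / "fly_tree.nwk")
        system.host_tree.write(outdir / "host_tree.nwk")
        system.truth.to_json(outdir / "truth.json")
        manifest["stages"]["simulate"] = {
            "files": ["associations.tsv", "fly_tree.nwk", "host_tree.nwk", "truth.json"]
        }
        return system.table, system.fly_tree, system.host_tree
    table = (
        assoc.load_association_table(config.associations)
        if config.associations
        else None
    )
    fly_tree = PhyloTree.from_file(config.fly_tree) if config.fly_tree else None
    host_tree = PhyloTree.from_file(config.host_tree) if config.host_tree else None
    if table is None:
        raise ValueError("no association table: give a path or a simulate preset")
    return table, fly_tree, host_tree


def _signal_row(tree, trait, character, n_poly, n_perm, seed) -> dict:
    k_res = phylosignal.blomberg_k_test(tree, trait, n_perm=n_perm, seed=seed,
                                        character=character)
    l_res = phylosignal.pagel_lambda_test(tree, trait, character=character)
    return {
        "character": character,
        "n_polyphages": n_poly,
        "blomberg_K": round(k_res.statistic, 6),
        "p_K": k_res.p_value,
        "pagel_lambda": round(l_res.statistic, 6),
        "p_lambda": l_res.p_value,
    }


def _stage_signal(config, table, fly_tree, profile, outdir: Path) -> None:
    seed = stage_seed(config.seed, "signal")
    tips = set(fly_tree.tip_labels)
    if set(profile.index) != tips:
        raise ValueError(
            "fly tree tips and association-table flies differ: "
            f"missing={sorted(tips - set(profile.index))}, "
            f"extra={sorted(set(profile.index) - tips)}"
        )
    rows = []
    cont = profile["n_host_families"].astype(float).to_dict()
    rows.append(_signal_row(fly_tree, cont, "continuous", None, config.n_perm, seed))
    for thr in config.polyphagy_thresholds:
        trait, count = assoc.binarize_polyphagy(profile, thr)
        rows.append(
            _signal_row(
                fly_tree,
                trait.astype(float).to_dict(),
                f"more_than_{thr}_families",
                count,
                config.n_perm,
                stage_seed(config.seed, f"signal-{thr}"),
            )
        )
    pd.DataFrame(rows).to_csv(outdir / "signal_table.tsv", sep="\t", index=False)


def _stage_sharing(config, table, host_tree, outdir: Path) -> None:
    matrix = assoc.interaction_matrix(table)
    distances = patristic_distances(host_tree)
    fit = host_sharing.resample_regression(
        matrix,
        distances,
        n_runs=config.n_runs,
        min_hosts=config.min_hosts,
        seed=stage_seed(config.seed, "sharing"),
    )
    fit.runs.to_csv(outdir / "sharing_runs.tsv", sep="\t", index=False)
    with open(outdir / "sharing_summary.json", "w") as fh:
        json.dump(fit.to_dict(), fh, indent=2)
    grid = np.linspace(0.0, float(np.max(distances.values)), 101)
    pd.DataFrame(
        {"distance_myr": grid, "p_sharing": host_sharing.sharing_probability(fit, grid)}
    ).to_csv(outdir / "sharing_curve.tsv", sep="\t", index=False)


def _stage_dec(config, table, chronogram, outdir: Path) -> None:
    families = assoc.main_host_families(table, k=config.k_main_families)
    filtered, retained = assoc.filter_for_dec(
        table, max_families=config.dec_max_families, exclude=config.dec_exclude
    )
    # flies whose whole diet falls outside the main families cannot carry a
    # DEC range; drop them like the study system's oleander-type specialists
    fams_by_fly = filtered.valid_records.groupby("fly_species")["host_family"].agg(set)
    outside = sorted(f for f, s in fams_by_fly.items() if not (s & set(families)))
    if outside:
        logger.info("dropping flies with no host among main families: %s", outside)
        filtered, retained = assoc.filter_for_dec(
            table,
            max_families=config.dec_max_families,
            exclude=tuple(config.dec_exclude) + tuple(outside),
        )
    (outdir / "dec_retained_flies.txt").write_text("\n".join(retained) + "\n")
    tips = assoc.tip_range_states(filtered, families)
    sub = _subtree(chronogram, retained)
    space = decmod.build_state_space(families, config.max_range_size)
    fit = decmod.fit_dec(sub, tips, space)
    est = decmod.ancestral_states(sub, tips, fit.params, space)
    with open(outdir / "dec_params.json", "w") as fh:
        json.dump(
            {
                "d": fit.params.d,
                "e": fit.params.e,
                "loglik": fit.loglik,
                "at_bound": fit.at_bound,
                "families": families,
                "n_states": space.n_states,
                "n_flies": len(retained),
            },
            fh,
            indent=2,
        )
    est.to_dataframe(top=5).to_csv(outdir / "dec_node_states.tsv", sep="\t", index=False)
    (outdir / "dec_annotated.nwk").write_text(
        decmod.annotated_newick(sub, est) + "\n"
    )


def _subtree(tree: PhyloTree, keep: list[str]) -> PhyloTree:
    """Prune the tree down to the retained tips (branch lengths preserved)."""
    dt = tree.copy().dendropy_tree
    taxa = [l.taxon for l in dt.leaf_node_iter() if l.taxon.label in set(keep)]
    if len(taxa) < len(set(keep)):
        have = {t.label for t in taxa}
        raise ValueError(f"tips absent from the tree: {sorted(set(keep) - have)}")
    dt.retain_taxa(taxa)
    dt.purge_taxon_namespace()
    return PhyloTree(dt)
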