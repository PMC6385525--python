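"""End-to-end orchestration: simulate -> ingest -> filter -> rare + burden.

One YAML config drives a reproducible run.  The workflow has a shared QC
front end (site quality, strand bias) after which it branches:

* rare-variant branch: recurrence -> control exclusion -> exonic class ->
  MAF < 0.001 -> CADD-ranked prioritisation;
* burden branch: exonic class -> MAF < 0.1 -> per-gene burden test against
  every panel, unrestricted and restricted to described missense variants.

Both branches consume the same post-QC variant set (asserted at the branch
point).  Every run writes report TSVs, per-branch filter ledgers and a
machine-readable manifest that is byte-identical on re-run with the same
config.
"""

from __future__ import annotations

import copy
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .burden import GeneBurdenModel, prioritize_rare_variants
from .exceptions import ConfigurationError
from .filters import (
    FilterLedger,
    control_exclusion_filter,
    functional_class_filter,
    maf_threshold_filter,
    recurrence_filter,
    site_quality_filter,
    strand_bias_filter,
)
from .io import (
    attach_panel_frequencies,
    merge_annotations,
    read_pooled_vcf,
    read_reference_panel,
    write_annotations_tsv,
    write_panels_tsv,
    write_pooled_vcf,
)
from .simulate import CohortConfig, n_pools, simulate_cohort
from .variants import EXONIC_CLASSES

DEFAULT_CONFIG: dict = {
    "schema_version": 1,
    "seed": 0,
    "cohort": {},  # CohortConfig overrides
    "filters": {
        "min_rd": 10,
        "min_gq": 20,
        "min_alt_reads_per_strand": 1,
        "min_pools": 2,
        "exonic_classes": sorted(EXONIC_CLASSES),
    },
    "rare": {"max_maf": 0.001, "panel": "global", "cadd_cut": None},
    "burden": {
        "max_maf": 0.1,
        "panel": "global",
        "spanish_panel": "spanish",
        "restrict_to_described_missense": True,
    },
    # optional: run on user-supplied files instead of the simulator
    # "inputs": {"vcf": ..., "annotations": ...,
    #            "panels": [{"path":..., "name":..., "n_individuals":...}]}
}


def load_config(source: str | os.PathLike | dict | None) -> dict:
    """Merge a YAML file / dict over the default config (two-level merge)."""
    config = copy.deepcopy(DEFAULT_CONFIG)
    if source is None:
        return config
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            overrides = yaml.safe_load(fh) or {}
    else:
        overrides = copy.deepcopy(source)
    if not isinstance(overrides, dict):
        raise ConfigurationError("config must be a mapping")
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(config.get(key), dict):
            config[key].update(value)
        else:
            config[key] = value
    return config


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()


@dataclass
class RunManifest:
    """Machine-readable record of one pipeline run."""

    version: str
    seed: int
    config_hash: str
    n_case_pools: int
    n_control_pools: int
    stages: dict[str, list] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config_hash": self.config_hash,
            "n_case_pools": self.n_case_pools,
            "n_control_pools": self.n_control_pools,
            "stages": self.stages,
            "outputs": self.outputs,
        }

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def _prepare_inputs(config: dict, out_dir: Path):
    """Simulate (default) or load user-supplied inputs.

    Simulated inputs are round-tripped through their on-disk formats so a run
    exercises the same readers a file-based run does.
    """
    inputs = config.get("inputs")
    if inputs:
        records = read_pooled_vcf(inputs["vcf"])
        records = merge_annotations(records, inputs["annotations"])
        panels = {}
        for spec in inputs["panels"]:
            panel = read_reference_panel(
                spec["path"], spec["name"], spec["n_individuals"]
            )
            panels[panel.name] = panel
        cohort_cfg = CohortConfig(**config.get("cohort", {}))
        return records, panels, cohort_cfg, None

    cohort_cfg = CohortConfig(**{"seed": config["seed"], **config.get("cohort", {})})
    sim = simulate_cohort(cohort_cfg)

    vcf_path = out_dir / "simulated_calls.vcf"
    panels_path = out_dir / "panels.tsv"
    ann_path = out_dir / "annotations.tsv"
    truth_path = out_dir / "truth.json"
    write_pooled_vcf(sim.records, vcf_path)
    write_panels_tsv(sim.panels.values(), panels_path)
    write_annotations_tsv(sim.annotations(), ann_path)
    sim.truth.to_json(truth_path)

    records = read_pooled_vcf(vcf_path)
    records = merge_annotations(records, ann_path)
    panels = {
        name: read_reference_panel(panels_path, name, panel.n_individuals)
        for name, panel in sim.panels.items()
    }
    written = {
        "simulated_calls": vcf_path.name,
        "panels": panels_path.name,
        "annotations": ann_path.name,
        "truth": truth_path.name,
    }
    return records, panels, cohort_cfg, written


def run_all(
    config: str | os.PathLike | dict | None,
    out_dir: str | os.PathLike,
    seed: int | None = None,
) -> RunManifest:
    """Execute both branches of the workflow; returns the run manifest."""
    config = load_config(config)
    if seed is not None:
        config["seed"] = int(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records, panels, cohort_cfg, written = _prepare_inputs(config, out_dir)
    outputs = dict(written or {})

    fcfg = config["filters"]
    for branch_cfg in (config["rare"], config["burden"]):
        if branch_cfg["panel"] not in panels:
            raise ConfigurationError(
                f"panel {branch_cfg['panel']!r} not available; "
                f"have: {sorted(panels)}"
            )

    records = attach_panel_frequencies(records, panels.values())

    # shared QC front end
    shared = FilterLedger()
    qc = site_quality_filter(
        records, min_rd=fcfg["min_rd"], min_gq=fcfg["min_gq"], ledger=shared
    )
    qc = strand_bias_filter(
        qc,
        min_alt_reads_per_strand=fcfg["min_alt_reads_per_strand"],
        ledger=shared,
    )

    branch_a_input = list(qc)
    branch_b_input = list(qc)
    assert {r.key for r in branch_a_input} == {r.key for r in branch_b_input}

    # rare-variant branch
    ledger_rare = FilterLedger(stages=list(shared.stages))
    rare = recurrence_filter(
        branch_a_input, min_pools=fcfg["min_pools"], ledger=ledger_rare
    )
    rare = control_exclusion_filter(rare, ledger=ledger_rare)
    rare = functional_class_filter(
        rare, keep=set(fcfg["exonic_classes"]), ledger=ledger_rare
    )
    rare = maf_threshold_filter(
        rare,
        panels[config["rare"]["panel"]],
        config["rare"]["max_maf"],
        ledger=ledger_rare,
    )
    ranked = prioritize_rare_variants(
        rare,
        cohort_cfg.n_cases,
        panels,
        maf_cut=config["rare"]["max_maf"],
        cadd_cut=config["rare"]["cadd_cut"],
    )
    rare_path = out_dir / "rare_variants.tsv"
    ranked.to_csv(rare_path, sep="\t", index=False, float_format="%.6g")
    ledger_rare.to_tsv(out_dir / "filter_ledger_rare.tsv")
    ledger_rare.to_json(out_dir / "filter_ledger_rare.json")

    # burden branch
    ledger_burden = FilterLedger(stages=list(shared.stages))
    burden_records = functional_class_filter(
        branch_b_input, keep=set(fcfg["exonic_classes"]), ledger=ledger_burden
    )
    burden_records = maf_threshold_filter(
        burden_records,
        panels[config["burden"]["panel"]],
        config["burden"]["max_maf"],
        ledger=ledger_burden,
    )
    model = GeneBurdenModel(
        burden_records,
        panels,
        cohort_cfg.n_cases,
        spanish_panel=config["burden"]["spanish_panel"],
    )
    unrestricted = model.fit(restrict_to_described_missense=False)
    unrestricted.to_tsv(out_dir / "burden_unrestricted.tsv")
    results = {"burden_unrestricted": unrestricted}
    if config["burden"]["restrict_to_described_missense"]:
        restricted = model.fit(restrict_to_described_missense=True)
        restricted.to_tsv(out_dir / "burden_restricted.tsv")
        results["burden_restricted"] = restricted
    ledger_burden.to_tsv(out_dir / "filter_ledger_burden.tsv")
    ledger_burden.to_json(out_dir / "filter_ledger_burden.json")

    outputs.update(
        {
            "rare_variants": rare_path.name,
            "burden_unrestricted": "burden_unrestricted.tsv",
            "filter_ledger_rare": "filter_ledger_rare.tsv",
            "filter_ledger_burden": "filter_ledger_burden.tsv",
        }
    )
    if "burden_restricted" in results:
        outputs["burden_restricted"] = "burden_restricted.tsv"

    manifest = RunManifest(
        version=__version__,
        seed=config["seed"],
        config_hash=config_hash(config),
        n_case_pools=n_pools(cohort_cfg.n_cases, cohort_cfg.pool_size),
        n_control_pools=n_pools(cohort_cfg.n_controls, cohort_cfg.pool_size),
        stages={
            "rare_branch": ledger_rare.counts(),
            "burden_branch": ledger_burden.counts(),
        },
        outputs=outputs,
    )
    manifest.to_json(out_dir / "manifest.json")
    return manifest
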