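"""Reproducible pipeline runs: simulate -> validate -> filter -> metrics -> report.

A run is configured by a YAML file with one block per stage spec plus global
toggles. Every stochastic stage must carry an explicit seed; unknown keys are
rejected up front. Stage outputs are plain delimited text / JSON in the run
directory, each stamped with the configuration hash, so a re-run with the
same config is byte-identical and partial stage lists re-use what is already
on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.spatial import cKDTree

from . import clones as clones_mod
from .candidates import FilterCriteria, filter_candidates
from .glomerular import assign_synapses, io_ratio_table, partner_demographics, \
    polarity_breakdown, ratio_matrix
from .imaging import quantify_trace, read_traces, write_traces
from .io import load_connectome, write_connectome
from .model import Connectome, InputError, SpecError, validate_connectome
from .morphometry import flow_centrality, to_dotprops
from .synthetic import CloneMatrixSpec, PopulationSpec, TraceSpec, \
    make_clone_matrix, make_connectome, make_trace

logger = logging.getLogger(__name__)

STAGES = ("simulate", "validate", "filter", "glom-metrics", "arbor-metrics",
          "clones", "imaging", "report")

_TOP_KEYS = {"output_dir", "population", "clones", "traces", "filter",
             "transmitter_map", "toggles"}
_TOGGLE_KEYS = {"holm_correction", "auc_window_from_onset", "nblast_sigma",
                "force_on_validation_failure", "smoothing_sigma",
                "bleach_correct"}


@dataclass
class RunConfig:
    output_dir: Path
    population: PopulationSpec
    clone_spec: CloneMatrixSpec
    trace_spec: TraceSpec
    criteria: FilterCriteria
    transmitter_map: dict[str, str] = field(default_factory=dict)
    toggles: dict = field(default_factory=dict)
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise SpecError(f"unknown config keys: {sorted(unknown)}")
        toggles = dict(raw.get("toggles") or {})
        unknown = set(toggles) - _TOGGLE_KEYS
        if unknown:
            raise SpecError(f"unknown toggle keys: {sorted(unknown)}")
        for block in ("population", "clones", "traces"):
            params = raw.get(block) or {}
            if "seed" not in params:
                raise SpecError(f"config block {block!r} must carry an explicit seed")
        pop = PopulationSpec(**(raw.get("population") or {}))
        cl = CloneMatrixSpec(**(raw.get("clones") or {}))
        tr = TraceSpec(**{k: v for k, v in (raw.get("traces") or {}).items()
                          if k != "glomeruli"})
        crit = FilterCriteria(**(raw.get("filter") or {}))
        return cls(
            output_dir=Path(raw.get("output_dir", "glomnet_run")),
            population=pop, clone_spec=cl, trace_spec=tr, criteria=crit,
            transmitter_map=dict(raw.get("transmitter_map") or {}),
            toggles=toggles, raw=raw,
        )


@dataclass
class RunReport:
    config_hash: str
    stages_run: list[str] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)
    notes: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config_hash": self.config_hash, "stages_run": self.stages_run,
             "artifacts": self.artifacts, "notes": self.notes},
            indent=2, sort_keys=True)


def _write_table(df: pd.DataFrame, path: Path, config_hash: str,
                 index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_table(path: Path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def synapse_sites_on_nodes(cn: Connectome, neuron: str) -> tuple[list[int], list[int]]:
    """Map a neuron's synapse sites to its nearest skeleton nodes.

    Returns (input node ids, output node ids) for flow-centrality analysis.
    """
    sk = cn.skeletons.get(neuron)
    if sk is None:
        raise InputError(f"neuron {neuron} has no skeleton")
    tree = cKDTree(sk.xyz)
    conns = cn.connections
    post = conns[conns["post_neuron"] == neuron][["post_x", "post_y", "post_z"]]
    pre = conns[conns["pre_neuron"] == neuron][["pre_x", "pre_y", "pre_z"]]
    inputs, outputs = [], []
    if len(post):
        _, idx = tree.query(post.to_numpy(float))
        inputs = [int(sk.node_ids[i]) for i in np.atleast_1d(idx)]
    if len(pre):
        _, idx = tree.query(pre.to_numpy(float))
        outputs = [int(sk.node_ids[i]) for i in np.atleast_1d(idx)]
    return inputs, outputs


class PipelineRunner:
    """Execute pipeline stages against one run directory."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.report = RunReport(config.config_hash)
        self._cn: Connectome | None = None
        self._truth = None

    # -- helpers -----------------------------------------------------------
    @property
    def connectome_dir(self) -> Path:
        return self.out / "connectome"

    def _connectome(self) -> Connectome:
        if self._cn is None:
            if not self.connectome_dir.is_dir():
                raise InputError(
                    "no connectome on disk; run the simulate stage first")
            self._cn = load_connectome(self.connectome_dir, validate=False)
        return self._cn

    def _candidates(self) -> list[str]:
        path = self.out / "filter_ledger.tsv"
        if not path.exists():
            raise InputError("no filter ledger on disk; run the filter stage first")
        final = json.loads((self.out / "candidates.json").read_text())
        return final["candidates"]

    # -- stages ------------------------------------------------------------
    def stage_simulate(self) -> None:
        cfg = self.config
        cn, truth = make_connectome(cfg.population)
        write_connectome(cn, self.connectome_dir)
        self._cn, self._truth = cn, truth
        (self.out / "ground_truth.json").write_text(json.dumps({
            "patchy_ids": truth.patchy_ids,
            "reference_ids": truth.reference_ids,
            "distractor_ids": truth.distractor_ids,
        }, indent=2))
        _write_table(truth.planted_io, self.out / "planted_io.tsv",
                     cfg.config_hash)

        matrix, achieved = make_clone_matrix(cfg.clone_spec)
        matrix.to_csv(self.out / "clone_matrix.tsv")
        _write_table(achieved, self.out / "clone_targets.tsv", cfg.config_hash,
                     index=True)

        glom_names = [s.name for s in truth.glomerulus_specs]
        traces = []
        for gi, g in enumerate(glom_names):
            for trial in range(3):
                spec = TraceSpec(**{**asdict(cfg.trace_spec),
                                    "seed": cfg.trace_spec.seed + 31 * gi + trial})
                traces.append(make_trace(
                    spec, metadata={"glomerulus": g, "animal": "sim", "trial": trial}))
        write_traces(traces, self.out / "traces.tsv")
        self.report.artifacts["connectome"] = str(self.connectome_dir)

    def stage_validate(self) -> None:
        report = validate_connectome(self._connectome())
        (self.out / "validation.json").write_text(
            json.dumps(report.to_dict(), indent=2))
        self.report.notes["validation_passed"] = report.passed
        if not report.passed and not self.config.toggles.get(
                "force_on_validation_failure", False):
            failures = [m for c in report.failures() for m in c.offenders]
            raise InputError("validation failed:\n" + "\n".join(failures))

    def stage_filter(self) -> None:
        cn = self._connectome()
        truth = json.loads((self.out / "ground_truth.json").read_text())
        refs = [to_dotprops(cn.skeletons[r]) for r in truth["reference_ids"]]
        criteria = self.config.criteria
        if criteria.marker_inputs is None:
            criteria = FilterCriteria(**{**asdict_criteria(criteria),
                                         "marker_inputs": ["CSD_L"]})
        ledger = filter_candidates(cn, refs, criteria)
        _write_table(ledger.to_frame(), self.out / "filter_ledger.tsv",
                     self.config.config_hash)
        (self.out / "candidates.json").write_text(json.dumps(
            {"candidates": ledger.candidates,
             "scores": {k: v for k, v in ledger.scores.items()
                        if np.isfinite(v)}}, indent=2))
        logger.info("filter ledger:\n%s", ledger.to_frame().to_string(index=False))

    def stage_glom_metrics(self) -> None:
        cn = self._connectome()
        candidates = self._candidates()
        assigned = assign_synapses(cn)
        table = io_ratio_table(cn, assigned, candidates)
        _write_table(table, self.out / "io_ratio.tsv", self.config.config_hash)
        _write_table(ratio_matrix(table), self.out / "io_ratio_matrix.tsv",
                     self.config.config_hash, index=True)
        demo = pd.concat([partner_demographics(cn, n, d)
                          for n in candidates for d in ("upstream", "downstream")],
                         ignore_index=True)
        _write_table(demo, self.out / "demographics.tsv", self.config.config_hash)
        polarity = pd.concat(
            [polarity_breakdown(cn, n, assigned).table for n in candidates],
            ignore_index=True)
        _write_table(polarity, self.out / "polarity.tsv", self.config.config_hash)

    def stage_arbor_metrics(self) -> None:
        cn = self._connectome()
        rows = []
        for nid in self._candidates():
            if nid not in cn.skeletons:
                continue
            inputs, outputs = synapse_sites_on_nodes(cn, nid)
            split = flow_centrality(cn.skeletons[nid], inputs, outputs)
            rows.append({
                "neuron_id": nid,
                "split_node": split.split_node,
                "segregation_index": split.segregation,
                "degenerate": split.degenerate,
                "n_inputs": len(inputs), "n_outputs": len(outputs),
            })
        _write_table(pd.DataFrame(rows), self.out / "arbor_split.tsv",
                     self.config.config_hash)

    def stage_clones(self) -> None:
        matrix = clones_mod.InnervationMatrix.from_csv(self.out / "clone_matrix.tsv")
        result = clones_mod.innervation_correlations(
            matrix, holm=self.config.toggles.get("holm_correction", False))
        _write_table(result.r, self.out / "clone_correlations_r.tsv",
                     self.config.config_hash, index=True)
        _write_table(result.p, self.out / "clone_correlations_p.tsv",
                     self.config.config_hash, index=True)
        order = clones_mod.ward_order(matrix, axis="rows")
        corder = clones_mod.ward_order(matrix, axis="columns")
        (self.out / "clone_order.json").write_text(json.dumps(
            {"rows": list(order), "columns": list(corder)}, indent=2))
        freq = clones_mod.innervation_frequency(matrix)
        _write_table(freq.rename("frequency").to_frame(),
                     self.out / "innervation_frequency.tsv",
                     self.config.config_hash, index=True)

    def stage_imaging(self) -> None:
        traces = read_traces(self.out / "traces.tsv")
        toggles = self.config.toggles
        rows = []
        for tr in traces:
            m = quantify_trace(
                tr,
                smoothing_sigma=toggles.get("smoothing_sigma", 1.0),
                bleach_correct=toggles.get("bleach_correct", True),
                window_from_onset=toggles.get("auc_window_from_onset", True),
            )
            rows.append({**tr.metadata, "f0": m.f0, "peak": m.peak, "auc": m.auc})
        per_trial = pd.DataFrame(rows)
        _write_table(per_trial, self.out / "imaging_trials.tsv",
                     self.config.config_hash)
        pooled = per_trial.groupby(["glomerulus", "animal"])[["peak", "auc"]].mean()
        _write_table(pooled.reset_index(), self.out / "imaging_metrics.tsv",
                     self.config.config_hash)

    def stage_report(self) -> None:
        (self.out / "run_report.json").write_text(self.report.to_json())

    def run(self, stages: list[str] | None = None) -> RunReport:
        stages = list(stages or STAGES)
        unknown = set(stages) - set(STAGES)
        if unknown:
            raise InputError(f"unknown stage name(s): {sorted(unknown)}")
        dispatch = {
            "simulate": self.stage_simulate,
            "validate": self.stage_validate,
            "filter": self.stage_filter,
            "glom-metrics": self.stage_glom_metrics,
            "arbor-metrics": self.stage_arbor_metrics,
            "clones": self.stage_clones,
            "imaging": self.stage_imaging,
            "report": self.stage_report,
        }
        for stage in STAGES:           # declared order, not caller order
            if stage in stages:
                logger.info("running stage %s", stage)
                dispatch[stage]()
                self.report.stages_run.append(stage)
        return self.report


def asdict_criteria(c: FilterCriteria) -> dict:
    return {"category": c.category, "subtype": c.subtype,
            "marker_inputs": c.marker_inputs,
            "nblast_threshold": c.nblast_threshold,
            "tracing_status": c.tracing_status}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> RunReport:
    """Run the requested stages (in canonical order) against the run directory."""
    return PipelineRunner(config).run(stages)
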