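"""Staged identification of candidate peptidergic LNs from a connectome.

The filter mirrors the field's candidate-selection recipe for picking a
neuropeptide-releasing interneuron ensemble out of a dense reconstruction:
keep local interneurons, keep the morphological subtype of interest
("patchy"), require synaptic input from a designated marker neuron set
(e.g. the serotonergic CSD neurons), require morphological similarity to a
reference driver-line library above an NBLAST threshold, and require the
highest tracing status. Every elimination is recorded in a ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .model import Connectome, SpecError
from .morphometry import DotProps, nblast_mean, to_dotprops


@dataclass
class FilterCriteria:
    """Ordered predicate chain for candidate identification.

    Stages run in the declared order (cheap annotation predicates before
    geometry). Any stage can be disabled by setting its parameter to None.
    """

    category: str | None = "LN"
    subtype: str | None = "patchy"
    marker_inputs: list[str] | None = None   # e.g. CSD neuron ids
    nblast_threshold: float | None = 0.80
    tracing_status: str | None = "Traced"

    def __post_init__(self) -> None:
        if self.nblast_threshold is not None and not (0.0 < self.nblast_threshold <= 1.0):
            raise SpecError(
                f"nblast_threshold must lie in (0, 1], got {self.nblast_threshold}"
            )
        if not any(v is not None for v in (
                self.category, self.subtype, self.marker_inputs,
                self.nblast_threshold, self.tracing_status)):
            raise SpecError("filter criteria must enable at least one stage")


@dataclass
class StageRecord:
    name: str
    survivors: int
    eliminated: list[str]


@dataclass
class FilterLedger:
    """Per-stage accounting of the candidate filter."""

    stages: list[StageRecord] = field(default_factory=list)
    candidates: list[str] = field(default_factory=list)
    scores: dict[str, float] = field(default_factory=dict)  # best NBLAST per neuron

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"stage": s.name, "survivors": s.survivors,
              "eliminated": ";".join(s.eliminated)} for s in self.stages]
        )


def filter_candidates(cn: Connectome,
                      references: list[DotProps] | None,
                      criteria: FilterCriteria,
                      dotprops: dict[str, DotProps] | None = None,
                      spacing: float = 1000.0) -> FilterLedger:
    """Apply the staged criteria; return the ledger with the final set.

    ``references`` supplies the driver-line morphology library for the NBLAST
    stage (each candidate is scored with the maximum mean-normalized score
    against any reference). Precomputed ``dotprops`` may be passed to avoid
    resampling skeletons twice.
    """
    if criteria.nblast_threshold is not None and not references:
        raise SpecError("NBLAST stage enabled but no reference morphology provided")

    ann = cn.annotations
    survivors = sorted(ann["neuron_id"])
    ledger = FilterLedger()

    def apply_stage(name: str, keep) -> None:
        nonlocal survivors
        kept, gone = [], []
        for nid in survivors:
            (kept if keep(nid) else gone).append(nid)
        ledger.stages.append(StageRecord(name, len(kept), gone))
        survivors = kept

    a = ann.set_index("neuron_id")
    if criteria.category is not None:
        apply_stage(f"category={criteria.category}",
                    lambda n: a.at[n, "category"] == criteria.category)
    if criteria.subtype is not None:
        apply_stage(f"subtype={criteria.subtype}",
                    lambda n: a.at[n, "subtype"] == criteria.subtype)
    if criteria.marker_inputs is not None:
        markers = set(criteria.marker_inputs)
        upstream = cn.connections[cn.connections["pre_neuron"].isin(markers)]
        with_marker_input = set(upstream["post_neuron"])
        apply_stage("marker_input", lambda n: n in with_marker_input)
    if criteria.nblast_threshold is not None:
        cache = dict(dotprops or {})

        def dp(n: str) -> DotProps | None:
            if n not in cache:
                sk = cn.skeletons.get(n)
                cache[n] = to_dotprops(sk, spacing=spacing) if sk is not None else None
            return cache[n]

        def best_score(n: str) -> float:
            q = dp(n)
            if q is None:
                return float("-inf")
            return max(nblast_mean(q, ref) for ref in references)

        for n in survivors:
            ledger.scores[n] = best_score(n)
        apply_stage(f"nblast>{criteria.nblast_threshold}",
                    lambda n: ledger.scores[n] > criteria.nblast_threshold)
    if criteria.tracing_status is not None:
        apply_stage(f"tracing_status={criteria.tracing_status}",
                    lambda n: a.at[n, "tracing_status"] == criteria.tracing_status)

    ledger.candidates = survivors
    return ledger
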