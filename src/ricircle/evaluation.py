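"""Simulation benchmarking: sensitivity and FDR of the detection pipeline.

Designed backsplice reads with known junctions are pushed through the full
pipeline (candidate selection -> pseudo-genome spliced alignment -> mate,
support and splice-signal filters); calls are matched one-to-one against
the designed truth set and aggregated over several independent data sets.

Conventions: sensitivity = recovered designed sites / designed sites;
FDR = calls matching no designed site / total calls, defined as 0 when no
calls are made.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .candidate_detection import GenomeIndex, PipelineConfig
from .circ_calling import CircRNACall
from .io_core import GeneModel, Genome
from .pipeline import detect
from .synthetic_data import SimConfig, TruthSet, simulate_backsplice_reads

log = logging.getLogger("ricircle")


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def match_junctions(calls: Sequence[CircRNACall], truth: TruthSet,
                    slack: int = 0) -> dict[str, object]:
    """One-to-one matching of calls to designed junctions.

    A call matches a truth entry when chromosome and strand agree and both
    endpoints differ by at most ``slack``.  Matching is greedy: calls in
    coordinate order claim their nearest (total endpoint offset) unmatched
    truth entry.  Returns matched pairs, recovered truth keys and the
    leftover (false-positive) calls.
    """
    if slack < 0:
        raise ValueError("slack must be >= 0")
    entries = list(truth.entries)
    if slack == 0:
        by_key = {e.key: i for i, e in enumerate(entries)}
        used: set[int] = set()
        pairs, fp = [], []
        for c in sorted(calls, key=lambda c: c.key):
            i = by_key.get(c.key)
            if i is not None and i not in used:
                used.add(i)
                pairs.append((c.id, entries[i].key))
            else:
                fp.append(c)
        return {"pairs": pairs, "recovered": {entries[i].key for i in used},
                "false_positives": fp}
    used = set()
    pairs, fp = [], []
    for c in sorted(calls, key=lambda c: c.key):
        best_i, best_d = None, None
        for i, e in enumerate(entries):
            if i in used or e.chrom != c.chrom or e.strand != c.strand:
                continue
            da, dd = abs(e.acceptor - c.start), abs(e.donor - c.end)
            if da <= slack and dd <= slack:
                d = da + dd
                if best_d is None or d < best_d:
                    best_i, best_d = i, d
        if best_i is None:
            fp.append(c)
        else:
            used.add(best_i)
            pairs.append((c.id, entries[best_i].key))
    return {"pairs": pairs, "recovered": {entries[i].key for i in used},
            "false_positives": fp}


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------

@dataclass
class DatasetResult:
    n_designed: int
    n_called: int
    n_recovered: int
    n_false: int
    reject_reasons: dict[str, int] = field(default_factory=dict)

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_designed if self.n_designed else 0.0

    @property
    def fdr(self) -> float:
        return self.n_false / self.n_called if self.n_called else 0.0


@dataclass
class EvalResult:
    per_dataset: list[DatasetResult]

    @property
    def n_designed(self) -> int:
        return sum(d.n_designed for d in self.per_dataset)

    @property
    def n_called(self) -> int:
        return sum(d.n_called for d in self.per_dataset)

    @property
    def n_recovered(self) -> int:
        return sum(d.n_recovered for d in self.per_dataset)

    @property
    def n_false(self) -> int:
        return sum(d.n_false for d in self.per_dataset)

    @property
    def sensitivity(self) -> float:
        return self.n_recovered / self.n_designed if self.n_designed else 0.0

    @property
    def fdr(self) -> float:
        return self.n_false / self.n_called if self.n_called else 0.0

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "fdr": self.fdr,
            "n_designed": self.n_designed,
            "n_called": self.n_called,
            "n_recovered": self.n_recovered,
            "n_false": self.n_false,
            "per_dataset": [
                {"n_designed": d.n_designed, "n_called": d.n_called,
                 "n_recovered": d.n_recovered, "n_false": d.n_false,
                 "sensitivity": d.sensitivity, "fdr": d.fdr,
                 "reject_reasons": d.reject_reasons}
                for d in self.per_dataset],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------

def run_simulation_study(
    models: Sequence[GeneModel],
    genome: Genome,
    cfg: SimConfig,
    pipeline_cfg: PipelineConfig | None = None,
    index: GenomeIndex | None = None,
    mate_mode: str = "inside",
) -> EvalResult:
    """The full simulation-testing experiment.

    Builds ``cfg.n_datasets`` independent designed-read data sets (seeds
    derived from ``cfg.rng_seed``), runs the complete detection pipeline
    on each, matches calls to the designed truth within
    ``pipeline_cfg.junction_slack``, and aggregates sensitivity and FDR.
    """
    pcfg = pipeline_cfg or PipelineConfig()
    if index is None:
        index = GenomeIndex(genome, pcfg.anchor_len)
    per_dataset: list[DatasetResult] = []
    for d in range(cfg.n_datasets):
        rng = np.random.default_rng((cfg.rng_seed * 1_000 + 17 * d) % (2**31 - 1))
        pairs, truth = simulate_backsplice_reads(models, genome, cfg, rng=rng,
                                                 mate_mode=mate_mode)
        if len(truth) == 0:
            raise ValueError("empty designed truth set")
        res = detect(genome, index, pairs, pcfg, sample=f"sim{d + 1}",
                     collect_rejections=True)
        matching = match_junctions(res.calls, truth, slack=pcfg.junction_slack)
        reasons: dict[str, int] = {}
        for k, v in res.funnel.items():
            if k.startswith("reject:"):
                reasons[k.split(":", 1)[1]] = v
        per_dataset.append(DatasetResult(
            n_designed=len(truth),
            n_called=len(res.calls),
            n_recovered=len(matching["recovered"]),
            n_false=len(matching["false_positives"]),
            reject_reasons=reasons,
        ))
        log.info("dataset %d: %d/%d designed sites recovered, %d/%d calls false",
                 d + 1, per_dataset[-1].n_recovered, len(truth),
                 per_dataset[-1].n_false, len(res.calls))
    return EvalResult(per_dataset)
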