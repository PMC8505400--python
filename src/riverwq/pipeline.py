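"""End-to-end assessment pipeline.

Orchestrates the study's analysis order for a validated sample collection:
per-sample indices with qualitative classes, a per-phase class-percentage
table, phase-to-phase comparison rows, correlation matrices per phase, and
one-way ANOVA with LSD across phases.  Every skipped index and data quirk
is logged with site/parameter context.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import compare as cmp
from . import indices as idx
from .errors import IncompleteIndexError
from .registry import PHASES, SampleRecord, StandardsTable

logger = logging.getLogger("riverwq")

__all__ = ["PipelineResults", "run_pipeline", "class_percentages"]

#: Default phase contrasts: lockdown-vs-pre and unlock-vs-pre.
DEFAULT_CONTRASTS = (("pre_lockdown", "lockdown"), ("pre_lockdown", "unlock"))

_INDEX_FUNCS = {
    "MWQI": idx.mwqi,
    "HPI": idx.hpi,
    "RI": idx.ri,
    "TSI": idx.tsi_from,
}


@dataclass
class PipelineResults:
    """Bundle of tidy tables produced by :func:`run_pipeline`."""

    indices: pd.DataFrame
    class_table: pd.DataFrame
    comparisons: dict[tuple[str, str], pd.DataFrame] = field(default_factory=dict)
    correlations: dict[str, pd.DataFrame] = field(default_factory=dict)
    anova: pd.DataFrame | None = None

    def write(self, outdir: str | Path) -> list[Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for name, frame in self._named_frames():
            path = outdir / f"{name}.csv"
            frame.to_csv(path, index=False)
            written.append(path)
        return written

    def _named_frames(self):
        yield "indices", self.indices
        yield "class_percentages", self.class_table
        for (a, b), frame in self.comparisons.items():
            yield f"comparison_{b}_vs_{a}", frame
        for phase, frame in self.correlations.items():
            yield f"correlation_{phase}", frame
        if self.anova is not None:
            yield "anova", self.anova


def _index_rows(samples: Sequence[SampleRecord], standards: StandardsTable):
    for rec in samples:
        for name, func in _INDEX_FUNCS.items():
            try:
                result = func(rec, standards)
            except IncompleteIndexError as exc:
                logger.info("%s/%s: %s", rec.site_id, rec.phase, exc)
                continue
            row = {
                "site_id": rec.site_id,
                "phase": rec.phase,
                "index_name": name,
                "value": result.value,
                "class_label": result.class_label,
            }
            row.update({f"c_{k}": v for k, v in result.components.items()})
            yield row


def class_percentages(index_frame: pd.DataFrame) -> pd.DataFrame:
    """Percent of samples in each qualitative class, per index per phase.

    Percentages are reported to two decimals (k/n × 100) and sum to 100
    within each index × phase.
    """
    rows = []
    for (phase, name), group in index_frame.groupby(["phase", "index_name"]):
        n = len(group)
        for label in idx.CLASS_ORDER[name]:
            k = int((group["class_label"] == label).sum())
            rows.append(
                {
                    "phase": phase,
                    "index_name": name,
                    "class_label": label,
                    "percent": round(k / n * 100.0, 2),
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    samples: Sequence[SampleRecord],
    standards: StandardsTable,
    contrasts: Sequence[tuple[str, str]] = DEFAULT_CONTRASTS,
    with_correlations: bool = True,
    with_anova: bool = True,
) -> PipelineResults:
    """Compute every result table for a validated sample collection."""
    index_frame = pd.DataFrame(list(_index_rows(samples, standards)))
    results = PipelineResults(
        indices=index_frame, class_table=class_percentages(index_frame)
    )

    by_phase: dict[str, list[SampleRecord]] = {}
    for rec in samples:
        by_phase.setdefault(rec.phase, []).append(rec)

    for a, b in contrasts:
        if a not in by_phase or b not in by_phase:
            logger.info("contrast %s vs %s skipped: phase missing", b, a)
            continue
        rows = cmp.compare_phases(by_phase[a], by_phase[b])
        results.comparisons[(a, b)] = pd.DataFrame([vars(r) for r in rows])

    if with_correlations:
        for phase, recs in by_phase.items():
            if len(recs) < 3:
                logger.info("correlations for %s skipped: n < 3", phase)
                continue
            cells = cmp.correlation_matrix(recs)
            results.correlations[phase] = pd.DataFrame([vars(c) for c in cells])

    if with_anova:
        phases = [p for p in PHASES if p in by_phase] or list(by_phase)
        codes = sorted(
            set.intersection(
                *(set(r.values) for p in phases for r in by_phase[p])
            )
        )
        anova_rows = []
        for code in codes:
            groups = {
                p: [r.values[code] for r in by_phase[p] if code in r.values]
                for p in phases
            }
            row = cmp.anova_lsd(groups, code)
            flat = {"code": code, "F": row.F, "p": row.p}
            flat.update(
                {f"lsd_{a}_vs_{b}": sep for (a, b), sep in row.lsd_pairs.items()}
            )
            anova_rows.append(flat)
        results.anova = pd.DataFrame(anova_rows)

    return results
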