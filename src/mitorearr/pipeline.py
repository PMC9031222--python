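"""Pipeline orchestration: comparison matrices, full-analysis runs, reports.

JSON reports are the canonical machine output, TSV for tables; every
report embeds the configuration, seed, conventions and package version so
reruns under an identical configuration are reproducible byte for byte
(timestamps are deliberately omitted).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from .annotation import (
    MitogenomeRecord,
    extract_isps,
    gene_order_of,
    spacer_table,
    summarize_dataset,
)
from .gene_order import (
    CLUSTER_ARNS1EF,
    CLUSTER_MIQ,
    GeneOrder,
    GeneOrderError,
    classify_arrangement,
    collapse_duplicates,
    registry,
    sci_percentage,
)
from .rearrangements import explain_duplication_pathway
from .simulate import SimConfig, generate_mitogenome

logger = logging.getLogger("mitorearr")
if not logger.handlers:  # stderr by default; a run log file is added per run
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Configuration recorded verbatim into every report."""

    inputs: list[str] = field(default_factory=list)
    anchor: str = "cox1"
    interval_convention: str = "size2"
    isp_scan_min_len: int = 15
    identity_floor: float = 70.0
    near_tie_pp: float = 2.0
    seed: int = 0
    outdir: str = "mitorearr-out"

    def provenance(self) -> dict:
        from . import __version__
        return {"config": asdict(self), "version": __version__}


def _hotspot_flags(orders: dict[str, GeneOrder]) -> dict[str, bool]:
    """True when an order's differences from MIQGO are confined to the two
    tRNA rearrangement hotspots (ARNS1EF and MIQ clusters)."""
    ref = registry()["MIQGO"]
    ref_names = ref.base_names()
    flags = {}
    hot = CLUSTER_ARNS1EF | CLUSTER_MIQ
    for name, order in orders.items():
        flat = collapse_duplicates(order)
        try:
            moved = {g for g, r in zip(flat.base_names(), ref_names) if g != r}
            moved |= {g for g, c in order.multiplicity().items() if c > 1}
        except GeneOrderError:
            flags[name] = False
            continue
        flags[name] = bool(moved) and moved <= hot or order.signature() == ref.signature()
    return flags


def run_compare(orders: dict[str, GeneOrder] | list[str],
                config: RunConfig | None = None
                ) -> tuple[pd.DataFrame, dict]:
    """SCI percentage matrix plus classification and hotspot report.

    ``orders`` is either a mapping name -> GeneOrder or a list of registry
    names.  Duplicate-bearing orders are collapsed (keep-plesiomorphic-
    position) before interval counting; the matrix is symmetric with a
    100% diagonal.
    """
    config = config or RunConfig()
    if isinstance(orders, list):
        reg = registry()
        unknown = [n for n in orders if n not in reg]
        if unknown:
            raise GeneOrderError(f"unknown registry names: {unknown}")
        orders = {n: reg[n] for n in orders}
    if len(orders) < 2:
        raise GeneOrderError("need at least two orders to compare")
    names = list(orders)
    flat = {n: collapse_duplicates(o) for n, o in orders.items()}
    mat = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            val = (100.0 if a == b else
                   sci_percentage(flat[a], flat[b],
                                  convention=config.interval_convention))
            mat.loc[a, b] = mat.loc[b, a] = val
    classification = {}
    for n, o in orders.items():
        try:
            label, nearest = classify_arrangement(o)
        except GeneOrderError:
            label, nearest = "incomplete", None
        classification[n] = {"arrangement": label, "nearest": nearest}
    report = {
        "sci_matrix": mat.to_dict(),
        "classification": classification,
        "hotspot_confined": _hotspot_flags(orders),
        "convention": config.interval_convention,
        "rounding": "half-up to integer percent",
        **config.provenance(),
    }
    return mat, report


def run_full(config: RunConfig, records: list[MitogenomeRecord] | None = None
             ) -> dict:
    """Execute all stages on provided or simulated records; write a report
    bundle (JSON + TSV) under ``config.outdir``.

    Stage failures are recorded in the report and dependent stages skipped;
    the function raises only on hard errors (empty input and no simulation
    request).
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    fh = logging.FileHandler(log_path, mode="w")
    logger.addHandler(fh)
    report: dict = {"stages": {}, **config.provenance()}
    try:
        if records is None:
            if not config.inputs:
                raise GeneOrderError(
                    "no input records and no arrangements to simulate")
            records = [generate_mitogenome(SimConfig(seed=config.seed + i,
                                                     arrangement=arr))
                       for i, arr in enumerate(config.inputs)]
        logger.info("analysing %d records", len(records))

        # stage: composition summary
        try:
            summary = summarize_dataset(records)
            summary.to_csv(outdir / "summary.tsv", sep="\t")
            report["stages"]["stats"] = "ok"
        except Exception as exc:  # recorded, not fatal
            report["stages"]["stats"] = f"failed: {exc}"

        # stage: gene orders + comparison
        orders = {}
        for rec in records:
            try:
                orders[rec.id] = gene_order_of(rec, config.anchor)
            except GeneOrderError as exc:
                logger.error("order derivation failed for %s: %s", rec.id, exc)
                report["stages"].setdefault("order_errors", {})[rec.id] = str(exc)
        if len(orders) >= 2:
            mat, cmp_report = run_compare(orders, config)
            mat.to_csv(outdir / "sci_matrix.tsv", sep="\t")
            report["compare"] = cmp_report
            report["stages"]["compare"] = "ok"
        else:
            report["stages"]["compare"] = "skipped: fewer than two orders"

        # stage: spacers
        isp_frames = []
        for rec in records:
            tab = spacer_table(extract_isps(rec))
            tab.insert(0, "record", rec.id)
            isp_frames.append(tab)
        pd.concat(isp_frames).to_csv(outdir / "isps.tsv", sep="\t", index=False)
        report["stages"]["isps"] = "ok"

        # stage: duplication pathways
        pathways = {}
        for rec in records:
            order = orders.get(rec.id)
            if order is None or not order.has_duplicates():
                continue
            try:
                pw = explain_duplication_pathway(rec)
                pathways[rec.id] = {
                    "events": [ev.kind for ev in pw.events],
                    "narrative": pw.narrative(),
                }
            except GeneOrderError as exc:
                report["stages"].setdefault("pathway_errors", {})[rec.id] = str(exc)
        report["duplication_pathways"] = pathways
        report["stages"]["pathways"] = "ok"

        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True, default=str))
        return report
    finally:
        logger.removeHandler(fh)
        fh.close()
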