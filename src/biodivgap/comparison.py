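"""Dataset-level summaries comparing the two occurrence sources.

Three summary layers:

* RecordSummary — record counts and percentages per source, cross-tabulated
  by taxon group, Red List category and threatened status; the share of all
  Threatened-species records held by each source; and the Least-Concern
  share within each source.
* OverlapSummary — species counts per source, species unique to one source,
  and species shared by both.
* ComparisonSummary — per-species EOO from each source with the difference
  (facebook − gbif), source-wise mean EOO, and the percentage of comparable
  species (ok status in both sources) whose facebook EOO is strictly larger,
  overall, for Threatened species, and per taxon group.

DD (Data Deficient) counts as nonthreatened in the threatened/nonthreatened
dichotomy but is also tabulated as its own category so no information is
lost. Percentages are kept unrounded internally and written to one decimal.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .eoo import B1_VULNERABLE_KM2, RangeEstimate
from .ingest import SOURCES, ChecklistEntry, OccurrenceRecord


@dataclass
class RecordSummary:
    n_records: dict[str, int]
    pct_records: dict[str, float]
    by_group: dict[tuple[str, str], int]          # (source, taxon_group) -> count
    by_category: dict[tuple[str, str], int]       # (source, category) -> count
    by_threatened: dict[tuple[str, bool], int]    # (source, threatened) -> count
    share_threatened_records: dict[str, float]    # source -> share of all Threatened records
    share_lc_within_source: dict[str, float]      # source -> LC fraction of own records


@dataclass
class OverlapSummary:
    species_per_source: dict[str, int]
    unique_to_source: dict[str, int]
    shared: int


@dataclass
class ComparisonSummary:
    per_species: pd.DataFrame  # species_id, taxon_group, threatened, eoo_fb,
                               # eoo_gbif, diff, status_fb, status_gbif
    mean_eoo: dict[str, float]
    pct_fb_larger: float | None
    pct_fb_larger_threatened: float | None
    pct_fb_larger_by_group: dict[str, float]
    n_comparable: int
    n_comparable_threatened: int


def _checklist_map(checklist: Sequence[ChecklistEntry]) -> dict[str, ChecklistEntry]:
    return {e.species_id: e for e in checklist}


def summarize_records(
    records: Sequence[OccurrenceRecord], checklist: Sequence[ChecklistEntry]
) -> RecordSummary:
    """Exhaustive record cross-tabulation; unknown species ids are an error."""
    by_sp = _checklist_map(checklist)
    offenders = sorted({r.species_id for r in records} - set(by_sp))
    if offenders:
        raise ValueError(f"records reference species absent from checklist: {offenders[:10]}")

    n_records = {s: 0 for s in SOURCES}
    by_group: dict[tuple[str, str], int] = {}
    by_category: dict[tuple[str, str], int] = {}
    by_threatened = {(s, t): 0 for s in SOURCES for t in (False, True)}
    for r in records:
        e = by_sp[r.species_id]
        n_records[r.source] = n_records.get(r.source, 0) + 1
        by_group[(r.source, e.taxon_group)] = by_group.get((r.source, e.taxon_group), 0) + 1
        by_category[(r.source, e.category)] = by_category.get((r.source, e.category), 0) + 1
        by_threatened[(r.source, e.threatened)] = by_threatened.get(
            (r.source, e.threatened), 0) + 1

    total = sum(n_records.values())
    pct = {s: (100.0 * n / total if total else 0.0) for s, n in n_records.items()}
    total_threat = sum(v for (s, t), v in by_threatened.items() if t)
    share_threat = {
        s: (by_threatened.get((s, True), 0) / total_threat if total_threat else 0.0)
        for s in n_records
    }
    share_lc = {
        s: (by_category.get((s, "LC"), 0) / n_records[s] if n_records[s] else 0.0)
        for s in n_records
    }
    return RecordSummary(n_records, pct, by_group, by_category, by_threatened,
                         share_threat, share_lc)


def species_overlap(records: Sequence[OccurrenceRecord]) -> OverlapSummary:
    """Set algebra on the species observed per source."""
    per_source: dict[str, set[str]] = {s: set() for s in SOURCES}
    for r in records:
        per_source.setdefault(r.source, set()).add(r.species_id)
    all_sets = list(per_source.values())
    shared = set.intersection(*all_sets) if all_sets else set()
    return OverlapSummary(
        species_per_source={s: len(v) for s, v in per_source.items()},
        unique_to_source={s: len(v - set.union(*(o for k, o in per_source.items() if k != s)))
                          if len(per_source) > 1 else len(v)
                          for s, v in per_source.items()},
        shared=len(shared),
    )


def _pct_larger(df: pd.DataFrame) -> float | None:
    if len(df) == 0:
        return None
    return 100.0 * float((df["diff"] > 0).sum()) / len(df)


def compare_eoo(
    estimates: Sequence[RangeEstimate], checklist: Sequence[ChecklistEntry]
) -> ComparisonSummary:
    """Join per-source EOO estimates per species and aggregate the differences.

    Means are computed over each source's ok estimates independently.
    Percentages of facebook-larger species use only species with ok status
    in both sources ("comparable"); difference > 0 is strict, so exact ties
    do not count as larger.
    """
    by_sp = _checklist_map(checklist)
    seen: set[tuple[str, str]] = set()
    per_sp: dict[str, dict[str, RangeEstimate]] = {}
    for est in estimates:
        key = (est.species_id, est.source)
        if key in seen:
            raise ValueError(f"duplicate estimate for {key}")
        seen.add(key)
        per_sp.setdefault(est.species_id, {})[est.source] = est

    rows = []
    for sp in sorted(per_sp):
        e = by_sp.get(sp)
        fb = per_sp[sp].get("facebook")
        gb = per_sp[sp].get("gbif")
        eoo_fb = fb.eoo_masked_km2 if fb and fb.status == "ok" else None
        eoo_gb = gb.eoo_masked_km2 if gb and gb.status == "ok" else None
        rows.append({
            "species_id": sp,
            "taxon_group": e.taxon_group if e else "other",
            "threatened": e.threatened if e else False,
            "eoo_fb": eoo_fb,
            "eoo_gbif": eoo_gb,
            "diff": (eoo_fb - eoo_gb) if eoo_fb is not None and eoo_gb is not None else None,
            "status_fb": fb.status if fb else "absent",
            "status_gbif": gb.status if gb else "absent",
        })
    df = pd.DataFrame(rows, columns=["species_id", "taxon_group", "threatened",
                                     "eoo_fb", "eoo_gbif", "diff",
                                     "status_fb", "status_gbif"])

    mean_eoo = {}
    for source, col in (("facebook", "eoo_fb"), ("gbif", "eoo_gbif")):
        vals = [est.eoo_masked_km2 for sp in per_sp.values()
                for est in [sp.get(source)] if est and est.status == "ok"]
        mean_eoo[source] = float(sum(vals) / len(vals)) if vals else float("nan")

    comp = df[df["diff"].notna()]
    threat = comp[comp["threatened"]]
    by_group = {}
    for g, sub in comp.groupby("taxon_group"):
        p = _pct_larger(sub)
        if p is not None:
            by_group[str(g)] = p
    return ComparisonSummary(
        per_species=df,
        mean_eoo=mean_eoo,
        pct_fb_larger=_pct_larger(comp),
        pct_fb_larger_threatened=_pct_larger(threat),
        pct_fb_larger_by_group=by_group,
        n_comparable=len(comp),
        n_comparable_threatened=len(threat),
    )


def _fmt_pct(v) -> str:
    return "" if v is None else f"{v:.1f}"


def write_summaries(summaries: dict, out_dir, manifest: dict | None = None) -> list[Path]:
    """Write deterministic CSV outputs plus a run manifest.

    ``summaries`` maps any of {"records", "overlap", "comparison"} to the
    corresponding summary object; ``manifest`` carries run provenance
    (seed, config hash, input checksums, grid cell size) and is written as
    manifest.json with the checksums of the files written here added.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    rs: RecordSummary | None = summaries.get("records")
    if rs is not None:
        rows = [{"source": s, "n_records": rs.n_records[s],
                 "pct_records": _fmt_pct(rs.pct_records[s]),
                 "share_threatened_records": f"{rs.share_threatened_records[s]:.4f}",
                 "share_lc_within_source": f"{rs.share_lc_within_source[s]:.4f}"}
                for s in sorted(rs.n_records)]
        p = out / "record_summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)
        xt = [{"source": s, "taxon_group": g, "n_records": n}
              for (s, g), n in sorted(rs.by_group.items())]
        p = out / "records_by_group.csv"
        pd.DataFrame(xt, columns=["source", "taxon_group", "n_records"]).to_csv(
            p, index=False)
        written.append(p)

    ov: OverlapSummary | None = summaries.get("overlap")
    if ov is not None:
        rows = [{"source": s, "n_species": ov.species_per_source[s],
                 "unique_species": ov.unique_to_source[s], "shared_species": ov.shared}
                for s in sorted(ov.species_per_source)]
        p = out / "overlap_summary.csv"
        pd.DataFrame(rows).to_csv(p, index=False)
        written.append(p)

    cmp: ComparisonSummary | None = summaries.get("comparison")
    if cmp is not None:
        p = out / "eoo_per_species.csv"
        df = cmp.per_species.copy()
        if len(df):
            df["below_b1_fb"] = df["eoo_fb"].map(
                lambda v: "" if pd.isna(v) else str(v < B1_VULNERABLE_KM2).lower())
            df["below_b1_gbif"] = df["eoo_gbif"].map(
                lambda v: "" if pd.isna(v) else str(v < B1_VULNERABLE_KM2).lower())
        else:
            df["below_b1_fb"] = pd.Series(dtype=str)
            df["below_b1_gbif"] = pd.Series(dtype=str)
        df.sort_values("species_id").to_csv(p, index=False)
        written.append(p)
        agg = {
            "mean_eoo_facebook_km2": cmp.mean_eoo.get("facebook"),
            "mean_eoo_gbif_km2": cmp.mean_eoo.get("gbif"),
            "pct_fb_larger": _fmt_pct(cmp.pct_fb_larger),
            "pct_fb_larger_threatened": _fmt_pct(cmp.pct_fb_larger_threatened),
            "n_comparable": cmp.n_comparable,
            "n_comparable_threatened": cmp.n_comparable_threatened,
        }
        p = out / "comparison_summary.csv"
        pd.DataFrame([agg]).to_csv(p, index=False)
        written.append(p)
        if cmp.pct_fb_larger_by_group:
            rows = [{"taxon_group": g, "pct_fb_larger": _fmt_pct(v)}
                    for g, v in sorted(cmp.pct_fb_larger_by_group.items())]
            p = out / "pct_fb_larger_by_group.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            written.append(p)

    manifest = dict(manifest or {})
    manifest["output_checksums"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in written}
    mp = out / "manifest.json"
    with open(mp, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    written.append(mp)
    return written


def checksum_file(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
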