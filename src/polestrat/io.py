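"""Readers, writers and the end-to-end pipeline report bundle.

All tables are plain TSV (UTF-8, 1-based coordinates throughout); the
catalog and domain map are JSON; the transcript is FASTA. Malformed cohort
rows are collected into a rejects report, never silently dropped. A JSON
manifest records the seed, thresholds, data sources and any skipped
stages so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .annotate import DdgRecord, NeoantigenScore, stability_census
from .signatures import (
    build_context_set,
    classify_variant_context,
    fraction_in_context,
    load_default_signatures,
    load_signature_table,
    POLE_SIGNATURES,
)
from .stats import ComparisonRefused, bh_fdr, mann_whitney
from .stratify import (
    TumorProfile,
    assign_groups,
    normalize_msi,
    summarize_groups,
)
from .variants import (
    CodingChange,
    DriverCatalog,
    DomainMap,
    PoleVariant,
    VariantParseError,
    expand_driver_catalog,
    flag_drivers,
    load_default_domain_map,
    load_default_driver_catalog,
    parse_hgvs_protein,
)

__all__ = [
    "CohortReadResult",
    "RunConfig",
    "read_cohort",
    "write_cohort",
    "read_ddg_table",
    "read_neoantigen_table",
    "run_pipeline",
]

REQUIRED_COLUMNS = ("tumor_id", "cancer_type", "tmb", "msi_status", "pole_variants")


@dataclass
class CohortReadResult:
    profiles: list[TumorProfile]
    rejects: list[dict]  # {"row": int, "tumor_id": str, "reason": str}


def _parse_coding(token: str) -> Optional[CodingChange]:
    t = token.strip()
    if not t or t == ".":
        return None
    if t.lower().startswith("c."):
        t = t[2:]
    # "123C>A"
    i = 0
    while i < len(t) and t[i].isdigit():
        i += 1
    if i == 0 or len(t) - i != 3 or t[i + 1] != ">":
        raise ValueError(f"bad coding change {token!r}")
    return CodingChange(position=int(t[:i]), ref=t[i].upper(), alt=t[i + 2].upper())


def _format_coding(c: Optional[CodingChange]) -> str:
    return "." if c is None else f"c.{c.position}{c.ref}>{c.alt}"


def read_cohort(path: str | Path, sep: Optional[str] = None) -> CohortReadResult:
    """Read a cohort TSV/CSV into validated :class:`TumorProfile` records.

    ``pole_variants`` holds semicolon-separated protein HGVS labels;
    ``coding_changes`` (optional) aligns with it positionally, using ``.``
    for variants without a coding-level call. Rows that fail validation
    land in the rejects report with the failing reason.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep or ("," if path.suffix == ".csv" else "\t"), dtype=str)
    if df.empty:
        raise ValueError(f"{path}: empty cohort file")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    profiles: list[TumorProfile] = []
    rejects: list[dict] = []
    for idx, row in df.iterrows():
        tumor_id = str(row.get("tumor_id", f"row{idx}"))
        try:
            labels = [t for t in str(row["pole_variants"]).split(";") if t.strip()]
            if not labels:
                raise ValueError("no POLE variants listed")
            codings = []
            raw_codings = row.get("coding_changes")
            if isinstance(raw_codings, str) and raw_codings.strip():
                codings = raw_codings.split(";")
                if len(codings) != len(labels):
                    raise ValueError(
                        f"{len(labels)} variants but {len(codings)} coding changes"
                    )
            variants = []
            for j, lab in enumerate(labels):
                v = parse_hgvs_protein(lab)
                if codings:
                    cc = _parse_coding(codings[j])
                    if cc is not None:
                        v = PoleVariant(
                            raw_label=v.raw_label, kind=v.kind, position=v.position,
                            end_position=v.end_position, ref_aa=v.ref_aa,
                            alt_aa=v.alt_aa, coding_change=cc,
                        )
                variants.append(v)
            comut = []
            raw_comut = row.get("comutations")
            if isinstance(raw_comut, str) and raw_comut.strip():
                for item in raw_comut.split(";"):
                    parts = item.split(":")
                    if len(parts) != 3:
                        raise ValueError(f"bad comutation entry {item!r}")
                    comut.append((parts[0], parts[1], parts[2]))
            age = row.get("age")
            sex = row.get("sex")
            pdl1 = row.get("pdl1")
            profiles.append(
                TumorProfile(
                    tumor_id=tumor_id,
                    cancer_type=str(row["cancer_type"]),
                    tmb=float(row["tmb"]),
                    msi_status=normalize_msi(row["msi_status"]),
                    age=float(age) if isinstance(age, str) and age.strip() else None,
                    sex=sex if isinstance(sex, str) and sex in ("F", "M") else "unknown",
                    pole_variants=tuple(variants),
                    comutations=tuple(comut),
                    pdl1=pdl1 if isinstance(pdl1, str) and pdl1.strip() else None,
                )
            )
        except (ValueError, VariantParseError) as exc:
            rejects.append({"row": int(idx), "tumor_id": tumor_id, "reason": str(exc)})
    return CohortReadResult(profiles=profiles, rejects=rejects)


def write_cohort(profiles: Sequence[TumorProfile], path: str | Path) -> None:
    """Write the same schema :func:`read_cohort` consumes (round-trips)."""
    rows = []
    for p in profiles:
        rows.append(
            {
                "tumor_id": p.tumor_id,
                "cancer_type": p.cancer_type,
                "tmb": f"{p.tmb:.1f}",
                "msi_status": p.msi_status,
                "age": "" if p.age is None else f"{p.age:.0f}",
                "sex": "" if p.sex == "unknown" else p.sex,
                "pole_variants": ";".join(v.raw_label for v in p.pole_variants),
                "coding_changes": ";".join(
                    _format_coding(v.coding_change) for v in p.pole_variants
                ),
                "comutations": ";".join(":".join(c) for c in p.comutations),
                "pdl1": p.pdl1 or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ddg_table(path: str | Path, cutoff: float = 1.45) -> list[DdgRecord]:
    """Read a (variant, model, ddg) TSV and classify each record."""
    df = pd.read_csv(path, sep="\t")
    for col in ("variant", "model", "ddg"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    records = []
    for _, row in df.iterrows():
        v = parse_hgvs_protein(str(row["variant"]))
        records.append(
            DdgRecord.build(
                variant_label=v.raw_label, position=v.position,
                ddg=float(row["ddg"]), model=str(row["model"]), cutoff=cutoff,
            )
        )
    return records


def read_neoantigen_table(path: str | Path, threshold: float = 0.5) -> pd.DataFrame:
    """Read per-tumor neoantigen scores and attach categories."""
    df = pd.read_csv(path, sep="\t")
    needed = ("tumor_id", "gene", "aa_change", "mhc_binding", "tcell_reactivity")
    for col in needed:
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    scores = [
        NeoantigenScore.build(
            gene=str(r["gene"]), aa_change=str(r["aa_change"]),
            hla_class=str(r.get("hla_class", "")), peptide=str(r.get("peptide", "")),
            mhc_binding=float(r["mhc_binding"]),
            tcell_reactivity=float(r["tcell_reactivity"]), threshold=threshold,
        )
        for _, r in df.iterrows()
    ]
    df = df.copy()
    df["category"] = [s.category for s in scores]
    return df


@dataclass
class RunConfig:
    """Paths and thresholds for one end-to-end run."""

    cohort_path: str | Path
    output_dir: str | Path
    catalog_path: Optional[str | Path] = None
    domain_map_path: Optional[str | Path] = None
    signature_path: Optional[str | Path] = None
    transcript_path: Optional[str | Path] = None
    ddg_path: Optional[str | Path] = None
    neoantigen_path: Optional[str | Path] = None
    tmb_threshold: float = 10.0
    inclusion_threshold: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.inclusion_threshold < 1):
            raise ValueError("inclusion threshold outside (0, 1)")
        if self.tmb_threshold <= 0:
            raise ValueError("TMB threshold must be positive")


def _load_catalog(cfg: RunConfig) -> DriverCatalog:
    if cfg.catalog_path is None:
        return load_default_driver_catalog()
    payload = json.loads(Path(cfg.catalog_path).read_text())
    return expand_driver_catalog(payload["drivers"])


def _load_domain_map(cfg: RunConfig) -> DomainMap:
    if cfg.domain_map_path is None:
        return load_default_domain_map()
    payload = json.loads(Path(cfg.domain_map_path).read_text())
    return DomainMap(
        protein_length=payload["protein_length"],
        lobes=tuple((d["name"], d["start"], d["end"]) for d in payload["lobes"]),
        domains=tuple((d["name"], d["start"], d["end"]) for d in payload["domains"]),
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run stratification, context, stats and annotation stages end to end.

    Returns the manifest (also written to ``manifest.json``); every output
    table is re-readable by this module's readers. Stages whose inputs are
    absent are skipped and the skip recorded in the manifest.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package": "polestrat",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "tmb_threshold": config.tmb_threshold,
        "inclusion_threshold": config.inclusion_threshold,
        "signature_source": str(config.signature_path or "bundled synthetic stand-in"),
        "outputs": [],
        "skipped": [],
    }

    def emit(name: str, df: pd.DataFrame) -> None:
        df.to_csv(outdir / name, sep="\t", index=True if df.index.nlevels > 1 else False)
        manifest["outputs"].append(name)

    # --- stratification -------------------------------------------------
    catalog = _load_catalog(config)
    domain_map = _load_domain_map(config)
    result = read_cohort(config.cohort_path)
    if result.rejects:
        pd.DataFrame(result.rejects).to_csv(outdir / "rejects.tsv", sep="\t", index=False)
        manifest["outputs"].append("rejects.tsv")
    manifest["n_profiles"] = len(result.profiles)
    manifest["n_rejects"] = len(result.rejects)
    profiles = result.profiles
    assignments = assign_groups(profiles, catalog, config.tmb_threshold)
    emit(
        "assignments.tsv",
        pd.DataFrame(
            {
                "tumor_id": p.tumor_id,
                "cancer_type": p.cancer_type,
                "tmb": p.tmb,
                "group": assignments[p.tumor_id].group,
                "substatus": assignments[p.tumor_id].substatus,
                "n_drivers": assignments[p.tumor_id].n_drivers,
                "n_additional_variants": assignments[p.tumor_id].n_additional_variants,
                "anomaly_flags": ",".join(sorted(assignments[p.tumor_id].anomaly_flags)),
            }
            for p in profiles
        ),
    )
    emit("group_summary.tsv", summarize_groups(profiles, assignments))

    # --- signature context (Group 3 non-driver variants) ----------------
    if config.signature_path is not None:
        signatures = load_signature_table(config.signature_path)
    else:
        signatures = load_default_signatures()
    if config.transcript_path is not None:
        from Bio import SeqIO

        record = next(SeqIO.parse(str(config.transcript_path), "fasta"))
        transcript = str(record.seq).upper()
    else:
        from .simulate import load_default_transcript

        transcript = load_default_transcript()
    sets = [
        build_context_set(signatures[s], config.inclusion_threshold)
        for s in POLE_SIGNATURES
        if s in signatures
    ]
    call_rows = []
    fractions = []
    for ct in sorted({p.cancer_type for p in profiles}):
        calls = []
        for p in profiles:
            if p.cancer_type != ct or assignments[p.tumor_id].group != "G3":
                continue
            flagged = flag_drivers(p.pole_variants, catalog)
            for v in flagged:
                if v.is_exod_driver:
                    continue
                call = classify_variant_context(v, sets, transcript)
                calls.append(call)
                call_rows.append(
                    {
                        "tumor_id": p.tumor_id,
                        "cancer_type": ct,
                        "variant": v.raw_label,
                        "channel": "" if call.channel is None else str(call.channel),
                        "in_pole_context": call.in_pole_context,
                        "matching_signatures": ",".join(sorted(call.matching_signatures)),
                        "hotspot_hit": ",".join(sorted(call.hotspot_hit)),
                    }
                )
        agg = fraction_in_context(calls)
        fractions.append(
            {
                "cancer_type": ct,
                "n_variants": agg.n_calls,
                "n_snv": agg.n_with_channel,
                "n_non_snv": agg.n_non_snv,
                "n_in_context": agg.n_in_context,
                "percent_in_context_snv": (
                    "" if agg.fraction is None else round(100 * agg.fraction, 1)
                ),
                "percent_in_context_all": (
                    "" if agg.fraction_all_variants is None
                    else round(100 * agg.fraction_all_variants, 1)
                ),
            }
        )
    emit("context_calls.tsv", pd.DataFrame(call_rows))
    emit("context_fractions.tsv", pd.DataFrame(fractions))

    # --- group statistics -----------------------------------------------
    stat_rows = []
    for ct in sorted({p.cancer_type for p in profiles}):
        tmb = {
            g: [
                p.tmb
                for p in profiles
                if p.cancer_type == ct and assignments[p.tumor_id].group == g
            ]
            for g in ("G1", "G2", "G3", "G4")
        }
        for ga, gb in (("G2", "G3"), ("G1", "G3")):
            try:
                res = mann_whitney(
                    tmb[ga], tmb[gb], label_a=f"{ct}/{ga}", label_b=f"{ct}/{gb}"
                )
                stat_rows.append(
                    {
                        "comparison": f"{ct}: {ga} vs {gb} TMB",
                        "n_a": res.n_a, "n_b": res.n_b,
                        "U": res.u_statistic, "p": res.p_value,
                        "method": res.method, "status": "ok",
                    }
                )
            except ComparisonRefused as exc:
                stat_rows.append(
                    {
                        "comparison": f"{ct}: {ga} vs {gb} TMB",
                        "n_a": len(tmb[ga]), "n_b": len(tmb[gb]),
                        "U": "", "p": "", "method": "", "status": str(exc),
                    }
                )
    stats_df = pd.DataFrame(stat_rows)
    ok = stats_df["status"] == "ok"
    if ok.any():
        adjusted = bh_fdr([float(p) for p in stats_df.loc[ok, "p"]])
        stats_df.loc[ok, "adjusted_p"] = adjusted
        from .stats import significance_stars

        stats_df.loc[ok, "stars"] = [significance_stars(p) for p in adjusted]
    emit("stats_report.tsv", stats_df)

    # --- annotation layers ----------------------------------------------
    if config.ddg_path is not None:
        records = read_ddg_table(config.ddg_path)
        census = stability_census(records, domain_map)
        census.to_csv(outdir / "stability_census.tsv", sep="\t")
        manifest["outputs"].append("stability_census.tsv")
    else:
        manifest["skipped"].append("stability_census (no ddg table)")

    if config.neoantigen_path is not None:
        neo = read_neoantigen_table(config.neoantigen_path)
        burden = (
            neo[neo["category"] == "immunogenic"]
            .groupby("tumor_id").size().rename("neoantigen_burden").reset_index()
        )
        all_tumors = neo[["tumor_id"]].drop_duplicates()
        burden = all_tumors.merge(burden, on="tumor_id", how="left").fillna(0)
        burden["neoantigen_burden"] = burden["neoantigen_burden"].astype(int)
        emit("neoantigen_burden.tsv", burden)
    else:
        manifest["skipped"].append("neoantigen_burden (no neoantigen table)")

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
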