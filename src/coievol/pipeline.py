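"""End-to-end orchestration of the comparative barcode analysis.

``run_pipeline`` drives the stages in their fixed order — QC/sampling,
family consensus, divergence metrics, Ka/Ks, indel events, trait ANOVA —
over either real inputs (aligned FASTA + taxonomy TSV + Newick tree +
outgroup FASTA) or a synthetic cohort generated in place from a SimConfig.
Every stage writes plain-text outputs into the run directory and the run
manifest records seeds, input digests and per-stage record counts, so a
rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from statistics import mean
from typing import Mapping

import pandas as pd

from . import __version__, anova, consensus, divergence, indels, io, kaks, qc
from .simulate import SimConfig, generate_cohort

log = logging.getLogger("coievol")

STAGES = ("qc", "consensus", "divergence", "kaks", "indels", "anova")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Declarative run description: exactly one of the real-input path group
    or the simulate block must be present."""

    outdir: str = "run"
    seed: int = 0
    records_fasta: str | None = None
    taxonomy_tsv: str | None = None
    tree_newick: str | None = None
    outgroups_fasta: str | None = None
    simulate: SimConfig | None = None
    stages: tuple[str, ...] = STAGES
    per_family_cap: int = 100
    subfamily_cap: int = 100
    min_bins: int = 3
    quartile_thresholds: tuple[float, float] | None = None
    ss_type: int = 2

    def validate(self) -> None:
        real = [self.records_fasta, self.taxonomy_tsv]
        if self.simulate is not None and any(p is not None for p in real):
            raise ConfigError("config contains both real inputs and a simulate block")
        if self.simulate is None and not all(p is not None for p in real):
            raise ConfigError(
                "config must provide either a simulate block or records_fasta "
                "+ taxonomy_tsv (with tree_newick/outgroups_fasta as needed)"
            )
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ConfigError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        if raw.get("simulate") is not None:
            raw["simulate"] = SimConfig.from_dict(raw["simulate"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if raw.get("quartile_thresholds") is not None:
            raw["quartile_thresholds"] = tuple(raw["quartile_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulate is not None:
            d["simulate"] = self.simulate.to_dict()
        d["stages"] = list(self.stages)
        if self.quartile_thresholds is not None:
            d["quartile_thresholds"] = list(self.quartile_thresholds)
        return d


def _family_alignments(records) -> dict[str, consensus.FamilyAlignment]:
    by_family: dict[str, dict[str, str]] = {}
    for rec in records:
        by_family.setdefault(rec.family, {})[rec.record_id] = rec.nt
    return {
        fam: consensus.FamilyAlignment(family=fam, rows=rows)
        for fam, rows in sorted(by_family.items())
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest (also written to
    ``manifest.json``).  A stage failure raises StageError but leaves the
    outputs of completed stages intact."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
        "inputs": {},
        "outputs": {},
    }

    # ----- inputs -----------------------------------------------------
    if config.simulate is not None:
        simdir = outdir / "cohort"
        cohort = generate_cohort(config.simulate, outdir=simdir)
        records = io.load_records(simdir / "records.fasta", simdir / "taxonomy.tsv")
        outgroup_seqs = cohort.outgroups
        tree = cohort.tree
        for name in ("records.fasta", "taxonomy.tsv", "tree.nwk", "outgroups.fasta",
                     "truth.json"):
            manifest["inputs"][name] = io.sha256_of(simdir / name)
    else:
        records = io.load_records(config.records_fasta, config.taxonomy_tsv)
        outgroup_seqs = (
            io.read_fasta(config.outgroups_fasta) if config.outgroups_fasta else {}
        )
        tree = io.read_tree(config.tree_newick) if config.tree_newick else None
        for key in ("records_fasta", "taxonomy_tsv", "tree_newick", "outgroups_fasta"):
            path = getattr(config, key)
            if path:
                manifest["inputs"][key] = io.sha256_of(path)

    def emit(name: str, path: Path) -> None:
        manifest["outputs"][name] = io.sha256_of(path)

    state: dict = {"records": records}

    # ----- stages -----------------------------------------------------
    try:
        if "qc" in config.stages:
            outcome = qc.run_qc(
                records,
                seed=config.seed,
                per_family_cap=config.per_family_cap,
                subfamily_cap=config.subfamily_cap,
                min_bins=config.min_bins,
            )
            state["records"] = outcome.records
            qc_df = pd.DataFrame([asdict(r) for r in outcome.reports])
            io.write_tsv(outdir / "qc_reports.tsv", qc_df)
            io.write_fasta(
                outdir / "qc_survivors.fasta",
                {r.record_id: r.nt for r in outcome.records},
            )
            (outdir / "qc_log.txt").write_text("\n".join(outcome.log) + "\n")
            manifest["stages"]["qc"] = {
                "attrition": outcome.attrition,
                "dropped_families": outcome.dropped_families,
            }
            emit("qc_reports.tsv", outdir / "qc_reports.tsv")
            emit("qc_survivors.fasta", outdir / "qc_survivors.fasta")
            for line in outcome.log:
                log.warning(line)
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", exc) from exc

    try:
        if "consensus" in config.stages:
            alignments = _family_alignments(state["records"])
            profiles = {f: consensus.build_consensus(a) for f, a in alignments.items()}
            insect = consensus.overall_consensus(profiles)
            state["profiles"] = profiles
            state["insect"] = insect
            out_profiles = {}
            for name in sorted(outgroup_seqs):
                out_profiles[name] = consensus.build_consensus(
                    consensus.FamilyAlignment(family=name, rows={name: outgroup_seqs[name]})
                )
            state["outgroup_profiles"] = out_profiles
            io.write_fasta(
                outdir / "consensus_nt.fasta",
                {f: p.nt_consensus for f, p in profiles.items()}
                | {insect.family: insect.nt_consensus},
            )
            io.write_fasta(
                outdir / "consensus_aa.fasta",
                {f: p.aa_consensus for f, p in profiles.items()}
                | {insect.family: insect.aa_consensus}
                | {n: p.aa_consensus for n, p in out_profiles.items()},
            )
            rows = []
            for fam, prof in profiles.items():
                row = {"family": fam}
                for name, op in out_profiles.items():
                    row[f"subs_vs_{name}"] = consensus.count_aa_substitutions(
                        prof.aa_consensus, op.aa_consensus
                    )
                rows.append(row)
            subs_df = pd.DataFrame(rows)
            io.write_tsv(outdir / "outgroup_substitutions.tsv", subs_df)
            state["subs_df"] = subs_df
            manifest["stages"]["consensus"] = {"n_families": len(profiles)}
            emit("consensus_nt.fasta", outdir / "consensus_nt.fasta")
            emit("consensus_aa.fasta", outdir / "consensus_aa.fasta")
            emit("outgroup_substitutions.tsv", outdir / "outgroup_substitutions.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("consensus", exc) from exc

    try:
        if "divergence" in config.stages and "profiles" in state:
            subs_df = state["subs_df"]
            count_cols = [c for c in subs_df.columns if c.startswith("subs_vs_")]
            div: dict = {}
            if len(count_cols) >= 2 and len(subs_df) >= 3:
                try:
                    div["outgroup_r2"] = divergence.outgroup_concordance(
                        subs_df[count_cols[0]], subs_df[count_cols[1]]
                    )
                except ValueError as err:
                    div["outgroup_r2"] = None
                    log.warning("outgroup concordance undefined: %s", err)
            primary = count_cols[0] if count_cols else None
            if primary and len(subs_df) >= 4:
                qc_counts = dict(zip(subs_df["family"], subs_df[primary]))
                classes = divergence.quartile_classes(
                    qc_counts, thresholds=config.quartile_thresholds
                )
                div["q1"], div["q3"] = classes.q1, classes.q3
                subs_df = subs_df.assign(
                    quartile_class=[classes.labels[f] for f in subs_df["family"]]
                )
                io.write_tsv(outdir / "family_divergence.tsv", subs_df)
                emit("family_divergence.tsv", outdir / "family_divergence.tsv")
            aa = {f: p.aa_consensus for f, p in state["profiles"].items()}
            pair_rows = [
                asdict(p) for p in divergence.pairwise_distances(aa)
            ]
            io.write_tsv(outdir / "pairwise_distances.tsv", pd.DataFrame(pair_rows))
            emit("pairwise_distances.tsv", outdir / "pairwise_distances.tsv")
            manifest["stages"]["divergence"] = div
            state["divergence"] = div
    except Exception as exc:  # noqa: BLE001
        raise StageError("divergence", exc) from exc

    try:
        if "kaks" in config.stages:
            by_family: dict[str, dict[str, str]] = {}
            for rec in state["records"]:
                by_family.setdefault(rec.family, {})[rec.bin_id] = rec.nt
            fam_results: dict[str, kaks.FamilyKaKs] = {}
            pair_rows, fam_rows = [], []
            for fam in sorted(by_family):
                fk = kaks.family_median_kaks(fam, by_family[fam])
                fam_results[fam] = fk
                fam_rows.append(
                    {
                        "family": fam,
                        "median_omega": fk.median_omega,
                        "n_pairs": fk.n_pairs,
                        "n_usable": fk.n_usable,
                    }
                )
                for r in fk.results:
                    pair_rows.append(
                        {
                            "family": fam,
                            "bin_a": r.pair[0],
                            "bin_b": r.pair[1],
                            "sd": r.sd,
                            "nd": r.nd,
                            "s_sites": r.s_sites,
                            "n_sites": r.n_sites,
                            "ka": r.ka,
                            "ks": r.ks,
                            "omega": r.omega,
                            "usable": r.usable,
                            "reason": r.reason,
                        }
                    )
            io.write_tsv(outdir / "kaks_pairs.tsv", pd.DataFrame(pair_rows))
            io.write_tsv(outdir / "kaks_families.tsv", pd.DataFrame(fam_rows))
            class_by_family = {
                rec.family: rec.traits.get("reproduction", "")
                for rec in state["records"]
            }
            class_omega = kaks.pooled_class_omega(fam_results, class_by_family)
            state["fam_results"] = fam_results
            state["class_omega"] = class_omega
            state["class_by_family"] = class_by_family
            with open(outdir / "class_omega.json", "w") as fh:
                json.dump(
                    {
                        "omega_by_class": class_omega.omega_by_class,
                        "n_pairs_by_class": class_omega.n_pairs_by_class,
                        "ratio_hd_dd": class_omega.ratio,
                    },
                    fh,
                    indent=1,
                    sort_keys=True,
                )
                fh.write("\n")
            manifest["stages"]["kaks"] = {
                "n_families": len(fam_results),
                "omega_by_class": class_omega.omega_by_class,
                "ratio_hd_dd": class_omega.ratio,
            }
            emit("kaks_pairs.tsv", outdir / "kaks_pairs.tsv")
            emit("kaks_families.tsv", outdir / "kaks_families.tsv")
            emit("class_omega.json", outdir / "class_omega.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("kaks", exc) from exc

    try:
        if "indels" in config.stages and "insect" in state and tree is not None:
            insect_aa = state["insect"].aa_consensus
            calls = {
                fam: indels.call_indels(p.aa_consensus, insect_aa)
                for fam, p in state["profiles"].items()
            }
            events = indels.collect_events(calls)
            class_by_family = state.get("class_by_family") or {
                rec.family: rec.traits.get("reproduction", "")
                for rec in state["records"]
            }
            order_by_family = {rec.family: rec.order for rec in state["records"]}
            summary = indels.classify_indels(events, class_by_family, order_by_family)
            counts = indels.min_event_count(events, tree, class_by_family)
            ev_rows = [
                {
                    "position": e.key.position,
                    "length": e.key.length,
                    "type": e.key.type,
                    "carriers": ",".join(sorted(e.carriers)),
                    "min_events": e.inferred_events,
                }
                for e in events
            ]
            io.write_tsv(outdir / "indel_events.tsv", pd.DataFrame(ev_rows))
            summary_all = {
                "summary": summary,
                "min_events_total": counts["total"],
                "min_events_by_class": counts.get("by_class", {}),
            }
            with open(outdir / "indel_summary.json", "w") as fh:
                json.dump(summary_all, fh, indent=1, sort_keys=True)
                fh.write("\n")
            state["indel_summary"] = summary_all
            manifest["stages"]["indels"] = summary_all
            emit("indel_events.tsv", outdir / "indel_events.tsv")
            emit("indel_summary.json", outdir / "indel_summary.json")
    except Exception as exc:  # noqa: BLE001
        raise StageError("indels", exc) from exc

    try:
        if "anova" in config.stages and "fam_results" in state:
            species = io.records_to_frame(state["records"])
            trait_table = anova.assign_traits(species)
            tf = trait_table.frame()
            tf["median_omega"] = [
                state["fam_results"][f].median_omega if f in state["fam_results"] else None
                for f in tf.index
            ]
            tf = tf.dropna(subset=["median_omega"])
            table = anova.type2_anova(
                tf, response="median_omega", ss_type=config.ss_type
            )
            out = table.reset_index().rename(columns={"index": "term"})
            io.write_tsv(outdir / "anova_table.tsv", out)
            manifest["stages"]["anova"] = {
                "n_families": int(len(tf)),
                "ties": trait_table.ties,
                "dropped_terms": table.attrs.get("dropped_terms", []),
            }
            state["anova_table"] = table
            emit("anova_table.tsv", outdir / "anova_table.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("anova", exc) from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------------
# reporting


_SECTIONS = {
    "record attrition": "manifest.json",
    "outgroup substitutions": "outgroup_substitutions.tsv",
    "median omega per family": "kaks_families.tsv",
    "class omega contrast": "class_omega.json",
    "indel summary": "indel_summary.json",
    "anova": "anova_table.tsv",
}


def report(run_dir: str | Path) -> str:
    """Human-readable summary of a completed run directory."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    missing = [n for n, f in _SECTIONS.items() if not (run_dir / f).exists()]
    if not manifest_path.exists():
        raise FileNotFoundError(
            f"{run_dir} has no manifest.json; missing sections: {sorted(_SECTIONS)}"
        )
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = [f"# coievol run report — {run_dir}", ""]

    lines.append("## Record attrition")
    attr = manifest.get("stages", {}).get("qc", {}).get("attrition")
    if attr:
        for stage, n in attr.items():
            lines.append(f"  {stage}: {n}")
    else:
        lines.append("  [skipped]")
    lines.append("")

    lines.append("## Outgroup substitutions (per-class means)")
    subs_path = run_dir / "outgroup_substitutions.tsv"
    kaks_path = run_dir / "kaks_families.tsv"
    if subs_path.exists():
        subs = pd.read_csv(subs_path, sep="\t")
        cols = [c for c in subs.columns if c.startswith("subs_vs_")]
        for c in cols:
            lines.append(f"  mean {c}: {subs[c].mean():.1f}")
        r2 = manifest.get("stages", {}).get("divergence", {}).get("outgroup_r2")
        if r2 is not None:
            lines.append(f"  outgroup concordance r^2: {r2:.3f}")
    else:
        lines.append("  [skipped]")
    lines.append("")

    lines.append("## Median Ka/Ks per family")
    if kaks_path.exists():
        fam = pd.read_csv(kaks_path, sep="\t")
        med = fam["median_omega"].dropna()
        lines.append(
            f"  {len(med)} families with defined omega; "
            f"median {med.median():.4f}, IQR [{med.quantile(0.25):.4f}, "
            f"{med.quantile(0.75):.4f}]"
        )
    else:
        lines.append("  [skipped]")
    lines.append("")

    lines.append("## Class omega contrast (HD vs DD)")
    co_path = run_dir / "class_omega.json"
    if co_path.exists():
        with open(co_path) as fh:
            co = json.load(fh)
        for cls, w in sorted(co["omega_by_class"].items()):
            lines.append(f"  omega_{cls}: {w:.4f}" if w is not None else f"  omega_{cls}: undefined")
        ratio = co.get("ratio_hd_dd")
        lines.append(f"  HD:DD ratio: {ratio:.2f}" if ratio else "  HD:DD ratio: undefined")
    else:
        lines.append("  [skipped]")
    lines.append("")

    lines.append("## Indel summary")
    ind_path = run_dir / "indel_summary.json"
    if ind_path.exists():
        with open(ind_path) as fh:
            ind = json.load(fh)
        s = ind["summary"]
        lines.append(
            f"  {s['total']} indels ({s['insertion']} insertions, "
            f"{s['deletion']} deletions); minimal events: {ind['min_events_total']}"
        )
        for cls, n in sorted(ind.get("min_events_by_class", {}).items()):
            lines.append(f"  minimal events in {cls} carriers: {n}")
    else:
        lines.append("  [skipped]")
    lines.append("")

    lines.append("## ANOVA (type-II SS)")
    an_path = run_dir / "anova_table.tsv"
    if an_path.exists():
        an = pd.read_csv(an_path, sep="\t")
        for row in an.itertuples(index=False):
            f = f"{row.F:.2f}" if pd.notna(row.F) else "-"
            p = f"{row._5:.3g}" if pd.notna(row._5) else "-"
            lines.append(f"  {row.term}: F={f}, p={p}")
    else:
        lines.append("  [skipped]")
    if missing:
        lines.append("")
        lines.append(f"(sections with missing outputs: {', '.join(sorted(missing))})")
    return "\n".join(lines) + "\n"
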