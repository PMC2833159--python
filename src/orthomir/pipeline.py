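"""Pipeline orchestration: families → predict → filter → conserve → evaluate.

A run is driven by a :class:`PipelineConfig` (YAML-round-trippable) and
writes stage TSVs, a Table-style evaluation report and a machine-readable
manifest (config hash, input checksums, per-stage counts) into a run
directory.  Stage outputs are nested: every pair surviving a stage survived
the previous one.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from orthomir import io as oio
from orthomir.duplex import DuplexHit, EnergyModel, screen_step1
from orthomir.families import MiRNAFamily, extract_conserved_families
from orthomir.features import FEATURE_NAMES, FilterParams, apply_filter, compute_features
from orthomir.optimizer import DEFAULT_GRID_SHAPE, coverage_curve, grid_search, grid_to_frame, select_ranges
from orthomir.ortho import ConservedPair, conserved_pairs
from orthomir.stats import control_experiment, stage_report

logger = logging.getLogger(__name__)

HIT_COLUMNS = [
    "mirna_id", "family", "species", "gene_id", "transcript_id",
    "site_start", "site_end", "seed_offset", "dG", "pairs_encoded",
    "dist_from_stop", "dist_from_3end", "utr_length", "mirna_len",
]


@dataclass
class PipelineConfig:
    """All numeric constants and paths of one screening run."""

    mirna_fasta: str = ""
    utr_fastas: dict[str, str] = field(default_factory=dict)  # species -> path
    ortholog_tsv: str = ""
    verified_tsv: str = ""
    whitelist: str | None = None
    outdir: str = "run"

    anchor_species: str = "H. sapiens"
    identity_threshold: float = 75.0
    dG_max: float = -17.0
    filter_params: tuple[int, int, int, int] = (12, 10, 4, 0)
    grid_shape: tuple[int, int, int, int] = DEFAULT_GRID_SHAPE
    min_species: int = 4
    longest_utr_per_gene: bool = True
    optimize_thresholds: bool = False
    run_control: bool = False
    n_control_per_species: int = 5
    control_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.filter_params = tuple(cfg.filter_params)
        cfg.grid_shape = tuple(cfg.grid_shape)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["filter_params"] = list(self.filter_params)
        data["grid_shape"] = list(self.grid_shape)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def hits_to_frame(hits: Sequence[DuplexHit], mirna_lengths: Mapping[str, int]) -> pd.DataFrame:
    rows = []
    for h in hits:
        rows.append(
            dict(
                mirna_id=h.mirna_id,
                family=h.family or h.mirna_id,
                species=h.species,
                gene_id=h.gene_id,
                transcript_id=h.transcript_id,
                site_start=h.site_start,
                site_end=h.site_end,
                seed_offset=h.seed_offset_label,
                dG=round(h.dG, 4),
                pairs_encoded=h.encode_pairs(),
                dist_from_stop=h.dist_from_stop,
                dist_from_3end=h.dist_from_3end,
                utr_length=h.utr_length,
                mirna_len=mirna_lengths[h.mirna_id],
            )
        )
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def frame_to_hits(df: pd.DataFrame) -> list[DuplexHit]:
    hits = []
    for row in df.itertuples(index=False):
        hits.append(
            DuplexHit(
                mirna_id=row.mirna_id,
                transcript_id=row.transcript_id,
                gene_id=row.gene_id,
                species=row.species,
                pairs=DuplexHit.decode_pairs(row.pairs_encoded),
                dG=float(row.dG),
                site_start=int(row.site_start),
                site_end=int(row.site_end),
                utr_length=int(row.utr_length),
                family=row.family,
                seed_offset_label=row.seed_offset,
            )
        )
    return hits


def features_from_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append the four binding-feature columns, recomputed from pairs_encoded."""
    feats = {name: [] for name in FEATURE_NAMES}
    for hit, mlen in zip(frame_to_hits(df), df["mirna_len"]):
        f = compute_features(hit, "A" * int(mlen))  # only the length matters here
        for name, v in zip(FEATURE_NAMES, f.as_tuple()):
            feats[name].append(v)
    out = df.copy()
    for name in FEATURE_NAMES:
        out[name] = feats[name]
    return out


def conserved_to_frame(pairs: Sequence[ConservedPair]) -> pd.DataFrame:
    rows = []
    for p in pairs:
        sites = ";".join(
            f"{sp}:{h.gene_id}:{h.site_start}-{h.site_end}:{h.dG:.2f}"
            for sp, h in sorted(p.per_species_hits.items())
        )
        rows.append(
            dict(
                family=p.family_name,
                cluster=p.cluster_id,
                anchor_gene=p.anchor_gene_id,
                n_species=p.n_species,
                species_list=",".join(sorted(p.species_with_site)),
                per_species_sites=sites,
            )
        )
    return pd.DataFrame(
        rows, columns=["family", "cluster", "anchor_gene", "n_species", "species_list", "per_species_sites"]
    )


def families_to_frame(families: Sequence[MiRNAFamily]) -> pd.DataFrame:
    rows = []
    for f in families:
        for m in f.members:
            rows.append(
                dict(
                    family=f.family_name,
                    species=m.species,
                    mirna_id=m.mirna_id,
                    seed_offset=f.shared_seed.offset_label,
                    identity_min_pct=round(f.identity_min_pct, 1),
                    identity_mean_pct=round(f.identity_mean_pct, 1),
                )
            )
    return pd.DataFrame(
        rows, columns=["family", "species", "mirna_id", "seed_offset", "identity_min_pct", "identity_mean_pct"]
    )


def report_to_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "stage": [r.stage_label for r in rows],
            "n_pred_kept": [r.n_pred_kept for r in rows],
            "n_pred_total": [r.n_pred_total for r in rows],
            "n_ver_kept": [r.n_ver_kept for r in rows],
            "n_ver_total": [r.n_ver_total for r in rows],
            "ratio_pred_pct": [round(r.ratio_pred_pct, 1) for r in rows],
            "ratio_ver_pct": [round(r.ratio_ver_pct, 1) for r in rows],
            "enrichment": [round(r.enrichment, 1) for r in rows],
        }
    )


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, model: EnergyModel | None = None) -> dict:
    """Execute the full screen; returns the manifest dict (also written to disk)."""
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    provenance = {"dG_max": config.dG_max, "filter_params": config.filter_params}

    # ---- inputs -------------------------------------------------------------
    mirnas = oio.read_mirna_fasta(config.mirna_fasta)
    by_species: dict[str, list] = {}
    for m in mirnas:
        by_species.setdefault(m.species, []).append(m)
    utrs: list = []
    for sp, path in sorted(config.utr_fastas.items()):
        utrs.extend(oio.read_utr_fasta(path, sp, longest_per_gene=config.longest_utr_per_gene))
    omap, verified = oio.read_tables(
        config.ortholog_tsv, config.verified_tsv, species=sorted(config.utr_fastas)
    )
    whitelist = None
    if config.whitelist:
        whitelist = [ln.strip() for ln in open(config.whitelist) if ln.strip() and not ln.startswith("#")]

    # ---- families -----------------------------------------------------------
    families = extract_conserved_families(
        by_species,
        identity_threshold=config.identity_threshold,
        family_whitelist=whitelist,
        anchor_species=config.anchor_species if config.anchor_species in by_species else None,
    )
    oio.write_tsv(families_to_frame(families), out / "families.tsv", provenance)
    logger.info("families: %d conserved (%.1fs)", len(families), time.time() - t0)

    mirna_lengths = {m.mirna_id: len(m) for m in mirnas}
    member_seq: dict[str, str] = {}
    screen_mirnas = []
    for fam in families:
        for m in fam.members:
            fm = dataclasses.replace(m, family=fam.family_name)
            screen_mirnas.append(fm)
            member_seq[fm.mirna_id] = fm.sequence

    # ---- step 1 -------------------------------------------------------------
    step1 = screen_step1(screen_mirnas, utrs, model, dG_max=config.dG_max)
    step1_df = hits_to_frame(step1, mirna_lengths)
    step1_df = features_from_frame(step1_df)
    oio.write_tsv(step1_df, out / "hits.step1.tsv", provenance)
    logger.info("step 1: %d hits (%.1fs)", len(step1), time.time() - t0)

    # ---- step 2 -------------------------------------------------------------
    verified_keys = {(f, g, s) for f, g, s in verified.pairs}
    flags = [
        (row.family, row.gene_id, row.species) in verified_keys
        for row in step1_df.itertuples(index=False)
    ]
    params = FilterParams(*config.filter_params)
    optimizer_out = None
    if config.optimize_thresholds and any(flags):
        curves = {name: coverage_curve(step1_df, flags, name) for name in FEATURE_NAMES}
        ranges = select_ranges(curves, config.grid_shape)
        points, best = grid_search(step1_df, flags, ranges)
        params = best.params
        oio.write_tsv(grid_to_frame(points), out / "grid.tsv", provenance)
        oio.write_tsv(
            pd.concat([c.to_frame() for c in curves.values()]), out / "curves.tsv", provenance
        )
        optimizer_out = {"best_params": list(params.as_tuple()), "best_ec": best.ec}
    step2_hits = []
    for hit in frame_to_hits(step1_df):
        f = compute_features(hit, member_seq[hit.mirna_id])
        if apply_filter(f, params):
            step2_hits.append(hit)
    step2_df = features_from_frame(hits_to_frame(step2_hits, mirna_lengths))
    oio.write_tsv(step2_df, out / "hits.step2.tsv", provenance)
    logger.info("step 2: %d hits (%.1fs)", len(step2_hits), time.time() - t0)

    # ---- step 3 -------------------------------------------------------------
    pairs = conserved_pairs(
        step2_hits, omap, min_species=config.min_species, anchor_species=config.anchor_species
    )
    oio.write_tsv(conserved_to_frame(pairs), out / "conserved_pairs.tsv", provenance)
    logger.info("step 3: %d conserved pairs (%.1fs)", len(pairs), time.time() - t0)

    # ---- evaluation ---------------------------------------------------------
    fam_names = [f.family_name for f in families]
    universe = {
        (fam, u.gene_id, u.species) for fam in fam_names for u in utrs
    }
    step1_set = {(r.family, r.gene_id, r.species) for r in step1_df.itertuples(index=False)}
    step2_set = {(h.family, h.gene_id, h.species) for h in step2_hits}
    step3_set = {
        (p.family_name, h.gene_id, sp)
        for p in pairs
        for sp, h in p.per_species_hits.items()
    }
    report_rows = []
    if verified_keys & universe:
        report_rows = stage_report(
            [
                ("STEP 1 (free energy and seed)", step1_set),
                ("STEP 2 (binding pattern)", step2_set),
                ("STEP 3 (ortholog conservation)", step3_set),
            ],
            universe,
            verified_keys,
        )
        oio.write_tsv(report_to_frame(report_rows), out / "evaluation.tsv", provenance)

    # ---- control ------------------------------------------------------------
    control = None
    if config.run_control and pairs:
        in_family = {m.mirna_id for f in families for m in f.members}
        control_candidates = {
            sp: [m for m in ms if m.mirna_id not in in_family]
            for sp, ms in by_species.items()
        }
        per_family_counts = pd.Series([p.family_name for p in pairs]).value_counts()
        conserved_counts = [int(per_family_counts.get(f, 0)) for f in fam_names]
        ctl = control_experiment(
            control_candidates, utrs, omap, conserved_counts,
            params=params, model=model, dG_max=config.dG_max,
            min_species=config.min_species, anchor_species=config.anchor_species,
            n_per_species=config.n_control_per_species, seed=config.control_seed,
        )
        control = {
            "per_mirna_counts_control": list(ctl.per_mirna_counts_control),
            "per_family_counts_conserved": list(ctl.per_mirna_counts_conserved),
            "mean_control": ctl.mean_control,
            "mean_conserved": ctl.mean_conserved,
            "t_stat": ctl.t_stat,
            "p_value": ctl.p_value,
            "n_zero_control": ctl.n_zero_control,
        }
        with open(out / "control.json", "w") as fh:
            json.dump(control, fh, indent=2)

    # ---- manifest -----------------------------------------------------------
    cfg_dict = dataclasses.asdict(config)
    cfg_dict["filter_params"] = list(config.filter_params)
    cfg_dict["grid_shape"] = list(config.grid_shape)
    input_paths = [config.mirna_fasta, config.ortholog_tsv, config.verified_tsv] + sorted(
        config.utr_fastas.values()
    )
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "inputs_sha256": {str(p): _sha256(p) for p in input_paths},
        "counts": {
            "families": len(families),
            "step1_hits": len(step1),
            "step2_hits": len(step2_hits),
            "conserved_pairs": len(pairs),
        },
        "applied_filter_params": list(params.as_tuple()),
        "optimizer": optimizer_out,
        "control": control,
        "evaluation": [
            dict(
                stage=r.stage_label,
                n_pred_kept=r.n_pred_kept,
                n_ver_kept=r.n_ver_kept,
                ratio_pred_pct=round(r.ratio_pred_pct, 1),
                ratio_ver_pct=round(r.ratio_ver_pct, 1),
                enrichment=round(r.enrichment, 1),
            )
            for r in report_rows
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("pipeline done in %.1fs", time.time() - t0)
    return manifest
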