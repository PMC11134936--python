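"""End-to-end orchestration of the two analysis arms.

``run_isotope_analysis`` reproduces the stable-isotope arm — nest
centroids, species summaries, within/between-nest distance ratios,
per-nest 95%-ellipse overlaps and the taxon/nest/interaction PERMANOVA
(under both candidate term orders).  ``run_microbiome_analysis`` runs
the audit-logged microbiome chain — decontamination, symbiotic
designation, endosymbiont subtraction, spike-in density, curation,
order-level composition with lifestyle PERMANOVA and BH post hocs,
and the strain-profile PERMANOVA.

Every run writes its outputs as CSV plus a plain-text report to the
output directory, records the root seed, and derives all per-stage
seeds from it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import amplicon as amp
from . import io as nio
from . import isotopes as iso
from . import permanova as pmv

__all__ = ["RunConfig", "run_isotope_analysis", "run_microbiome_analysis"]

logger = logging.getLogger("nestniche")

#: both candidate orders for the taxon/nest/interaction model
DEFAULT_TERM_ORDERS = (
    ("taxon", "nest", "taxon:nest"),
    ("nest", "taxon", "nest:taxon"),
)


@dataclass
class RunConfig:
    """Configuration shared by the two analysis arms."""

    isotope_path: str | None = None
    counts_path: str | None = None
    taxonomy_path: str | None = None
    meta_path: str | None = None
    output_dir: str = "nestniche_out"
    seed: int = 0
    n_permutations: int = 999
    overlap_convention: str = "union"
    restrict_to_host_taxon: bool = True
    fold: float = 10.0
    symbiotic_threshold: float = 0.001
    mean_count_threshold: float = 20.0
    variance_fraction: float = 0.10
    spike_copies: float = 1000.0
    detection_min_reads: int = 1
    top_n_orders: int = 9
    term_orders: tuple = DEFAULT_TERM_ORDERS

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        if "term_orders" in data:
            data["term_orders"] = tuple(tuple(t) for t in data["term_orders"])
        return cls(**data)


def _setup_output(config: RunConfig, arm: str) -> tuple[Path, list[str]]:
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    info = asdict(config)
    info["analysis_arm"] = arm
    (out / "run_info.json").write_text(json.dumps(info, indent=2, default=str))
    return out, []


def _stage_seeds(seed: int, n: int) -> list[int]:
    return [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n)
    ]


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text).strip("_")


def _write_report(out: Path, name: str, lines: list[str]) -> None:
    (out / name).write_text("\n".join(lines) + "\n")
    for ln in lines:
        logger.info(ln)


# ---------------------------------------------------------------------------
# Isotope arm
# ---------------------------------------------------------------------------


def run_isotope_analysis(
    config: RunConfig, panel: pd.DataFrame | None = None
) -> dict:
    """Run the stable-isotope arm; returns a dict of result tables.

    ``panel`` may be passed directly; otherwise it is read from
    ``config.isotope_path``.  Degenerate situations (a single nest, too
    few specimens for an ellipse) are skipped with explicit report
    entries instead of failing the whole run.
    """
    out, lines = _setup_output(config, "isotope")
    if panel is None:
        if config.isotope_path is None:
            raise ValueError("config.isotope_path is required")
        panel = nio.read_isotope_table(config.isotope_path)
    lines.append(f"isotope arm: {len(panel)} specimens, seed={config.seed}")

    centroids = iso.nest_averages(panel, "species")
    centroids.to_csv(out / "nest_centroids.csv", index=False)
    summary = iso.group_summary(centroids, "species")
    summary.to_csv(out / "species_summary.csv", index=False)
    results: dict = {"nest_centroids": centroids, "species_summary": summary}
    lines.append(
        f"nest centroids: {len(centroids)} (nest, species) groups; "
        f"species summaries over nest means: {len(summary)}"
    )

    sf = panel[panel["taxon_group"] == "silverfish"]
    lifestyles = sorted(sf["lifestyle"].dropna().unique())
    seeds = _stage_seeds(config.seed, max(len(lifestyles), 1) * len(config.term_orders))
    si = 0
    for style in lifestyles:
        tag = _slug(style)
        focal = {"taxon_group": "silverfish", "lifestyle": style}
        shared = sorted(
            set(sf.loc[sf["lifestyle"] == style, "nest_id"])
            & set(panel.loc[panel["taxon_group"] == "ant", "nest_id"])
        )
        shared = [n for n in shared if n]
        sub = panel[
            (panel["nest_id"].isin(shared))
            & (
                ((panel["taxon_group"] == "silverfish") & (panel["lifestyle"] == style))
                | (panel["taxon_group"] == "ant")
            )
        ]

        # within/between distance ratio
        try:
            ratio = iso.within_between_ratio(
                panel,
                focal,
                {"taxon_group": "ant"},
                restrict_to_host_taxon=config.restrict_to_host_taxon,
            )
            ratio.per_nest.to_csv(out / f"distance_ratio_{tag}.csv", index=False)
            results[f"distance_ratio_{style}"] = ratio
            lines.append(
                f"[{style}] distance ratio (between/within) = "
                f"{ratio.mean_ratio:.2f} +/- {ratio.se_ratio:.2f} SE over "
                f"{len(ratio.per_nest)} nests ({ratio.n_degenerate} degenerate)"
            )
        except ValueError as exc:
            lines.append(f"[{style}] distance-ratio stage skipped: {exc}")

        # per-nest ellipse overlap
        ov_rows = []
        for nest in shared:
            f_pts = sub[
                (sub["nest_id"] == nest) & (sub["taxon_group"] == "silverfish")
            ][["d13C", "d15N"]].to_numpy()
            h_pts = sub[(sub["nest_id"] == nest) & (sub["taxon_group"] == "ant")][
                ["d13C", "d15N"]
            ].to_numpy()
            if len(f_pts) < 3 or len(h_pts) < 3:
                lines.append(
                    f"[{style}] nest {nest}: ellipse overlap skipped "
                    f"(needs >= 3 points per group)"
                )
                continue
            try:
                ea = iso.fit_ellipse(f_pts)
                eb = iso.fit_ellipse(h_pts)
                ov = iso.ellipse_overlap(ea, eb, convention=config.overlap_convention)
            except ValueError as exc:
                lines.append(f"[{style}] nest {nest}: ellipse overlap skipped ({exc})")
                continue
            ov_rows.append(
                {
                    "nest_id": nest,
                    "area_silverfish": ov.area_a,
                    "area_host": ov.area_b,
                    "overlap_area": ov.overlap_area,
                    "percent": ov.percent,
                    "convention": ov.convention,
                }
            )
        if ov_rows:
            ov_df = pd.DataFrame(ov_rows)
            ov_df.to_csv(out / f"ellipse_overlap_{tag}.csv", index=False)
            results[f"ellipse_overlap_{style}"] = ov_df
            lines.append(
                f"[{style}] mean ellipse overlap ({config.overlap_convention}) = "
                f"{ov_df['percent'].mean():.1f}% over {len(ov_df)} nests"
            )

        # PERMANOVA under both term orders
        design = pd.DataFrame(
            {
                "taxon": sub["taxon_group"].to_numpy(),
                "nest": sub["nest_id"].to_numpy(),
            },
            index=sub["sample_id"].to_numpy(),
        )
        for order in config.term_orders:
            seed_k = seeds[si % len(seeds)]
            si += 1
            try:
                dm = iso.cn_distance_matrix(sub)
                res = pmv.permanova_sequential(
                    dm, design, list(order),
                    n_permutations=config.n_permutations, seed=seed_k,
                )
            except (ValueError, KeyError) as exc:
                lines.append(
                    f"[{style}] PERMANOVA ({' + '.join(order)}) skipped: {exc}"
                )
                continue
            fname = f"permanova_{tag}_{_slug('_'.join(order))}.csv"
            res.table.to_csv(out / fname)
            results[f"permanova_{style}_{order}"] = res
            r2 = {t: res.table.loc[t, "R2"] for t in order}
            lines.append(
                f"[{style}] PERMANOVA order {' + '.join(order)}: "
                + ", ".join(f"R2[{t}]={v:.3f}" for t, v in r2.items())
            )

    _write_report(out, "isotope_report.txt", lines)
    results["report_lines"] = lines
    return results


# ---------------------------------------------------------------------------
# Microbiome arm
# ---------------------------------------------------------------------------


def run_microbiome_analysis(
    config: RunConfig,
    counts: pd.DataFrame | None = None,
    taxonomy: pd.DataFrame | None = None,
    meta: pd.DataFrame | None = None,
) -> dict:
    """Run the microbiome arm; returns a dict of result tables.

    Missing blanks abort with an error naming the remedy; a missing
    spike-in flag only disables the density stage, everything else
    proceeds.
    """
    out, lines = _setup_output(config, "microbiome")
    if counts is None:
        counts = nio.read_count_table(config.counts_path)
        taxonomy = nio.read_taxonomy(config.taxonomy_path)
        meta = nio.read_sample_meta(config.meta_path)
    meta = meta.loc[counts.index]
    results: dict = {}
    seeds = _stage_seeds(config.seed, 4 + len(config.term_orders))
    lines.append(
        f"microbiome arm: {counts.shape[0]} samples x {counts.shape[1]} zOTUs, "
        f"seed={config.seed}"
    )

    # 1. relative abundance + decontamination
    ra = amp.relative_abundance(counts, taxonomy, exclude_spike=True)
    try:
        retained, dec_audit = amp.decontaminate(ra, meta, fold=config.fold)
    except ValueError as exc:
        raise ValueError(
            f"{exc}. Remedy: include at least one sample with role='blank' "
            f"in the metadata so the tenfold rule can be applied."
        ) from exc
    dec_audit.to_csv(out / "decontamination_audit.csv")
    removed = sorted(set(ra.data.columns) - set(retained))
    lines.append(
        f"decontamination (fold={config.fold:g}): {len(retained)} zOTUs retained, "
        f"{len(removed)} removed: {removed}"
    )
    results["decontamination_audit"] = dec_audit

    # 2. symbiotic designation
    ra_ret = amp.RAMatrix(ra.data[retained], ra.excluded, ra.basis)
    symbiotic = amp.designate_symbiotic(
        ra_ret, meta, threshold=config.symbiotic_threshold
    )
    lines.append(
        f"symbiotic designation (> {config.symbiotic_threshold:g}): "
        f"{len(symbiotic)} of {len(retained)} retained zOTUs"
    )
    results["symbiotic_zotus"] = symbiotic

    exp_ids = meta.index[meta["role"] == "experimental"]
    exp_counts = counts.loc[exp_ids, symbiotic]

    # 3. spike-in density (refuses gracefully without a spike flag)
    try:
        density = amp.spike_density(
            counts,
            taxonomy,
            meta,
            spike_copies=config.spike_copies,
            zotus=symbiotic,
        )
        density.to_csv(out / "density.csv")
        results["density"] = density
        ok = density.loc[~density["undefined"], "copies_per_ng"]
        lines.append(
            f"density: median {ok.median():.0f} copies/ng over {len(ok)} samples "
            f"({int(density['undefined'].sum())} undefined)"
        )
    except ValueError as exc:
        lines.append(f"density stage refused: {exc}")

    # 4. endosymbiont subtraction + curation
    sub_counts = amp.subtract_taxon_reads(exp_counts, taxonomy)
    n_sub = exp_counts.shape[1] - sub_counts.shape[1]
    lines.append(f"Anaplasmataceae subtraction: {n_sub} zOTU column(s) removed")
    try:
        curated, cur_audit = amp.curation_filter(
            sub_counts,
            mean_threshold=config.mean_count_threshold,
            low_variance_fraction=config.variance_fraction,
        )
    except ValueError as exc:
        lines.append(f"curation stage failed: {exc}")
        _write_report(out, "microbiome_report.txt", lines)
        results["report_lines"] = lines
        return results
    cur_audit.to_csv(out / "curation_audit.csv")
    results["curation_audit"] = cur_audit
    lines.append(
        f"curation (mean >= {config.mean_count_threshold:g}, "
        f"SD above the {config.variance_fraction:.0%} quantile): "
        f"{len(curated)} of {sub_counts.shape[1]} zOTUs retained"
    )

    # 5. order-level composition, lifestyle PERMANOVA, BH post hocs
    sf_ids = [s for s in exp_ids if meta.loc[s, "taxon_group"] == "silverfish"]
    if len(sf_ids) >= 3:
        comp = amp.order_composition(
            sub_counts.loc[sf_ids, curated],
            taxonomy,
            meta,
            top_n=config.top_n_orders,
            group_by=["nest_id", "lifestyle"],
        )
        comp.to_csv(out / "composition_nest_lifestyle.csv")
        results["composition"] = comp
        styles = comp.index.get_level_values("lifestyle")
        if styles.nunique() >= 2 and styles.value_counts().min() >= 2:
            bc = pmv.bray_curtis(
                comp.set_axis(range(len(comp)), axis=0)
            )
            design = pd.DataFrame({"lifestyle": styles.to_numpy()})
            res = pmv.permanova_sequential(
                bc, design, ["lifestyle"],
                n_permutations=config.n_permutations, seed=seeds[0],
            )
            res.table.to_csv(out / "permanova_composition_lifestyle.csv")
            results["composition_permanova"] = res
            lines.append(
                f"composition ~ lifestyle: R2={res.table.loc['lifestyle', 'R2']:.3f}, "
                f"p={res.table.loc['lifestyle', 'p_perm']:.4g}"
            )
            if styles.nunique() >= 3:
                pw = pmv.pairwise_permanova_bh(
                    bc,
                    pd.Series(styles.to_numpy(), index=bc.ids),
                    n_permutations=config.n_permutations,
                    seed=seeds[1],
                )
                pw.to_csv(out / "pairwise_composition_bh.csv", index=False)
                results["composition_pairwise"] = pw
        else:
            lines.append("composition PERMANOVA skipped: < 2 lifestyles with >= 2 groups")
    else:
        lines.append("composition stage skipped: < 3 silverfish samples")

    # 6. Weissella strain-profile PERMANOVA (both term orders)
    try:
        profile = amp.strain_profile(
            counts.loc[exp_ids, [z for z in curated if z in counts.columns]],
            taxonomy,
            detection_min_reads=config.detection_min_reads,
        )
    except ValueError as exc:
        profile = None
        lines.append(f"strain-profile stage skipped: {exc}")
    if profile is not None:
        target_style = "Messor-specialized"
        focal_nests = sorted(
            set(
                meta.loc[
                    (meta["lifestyle"] == target_style)
                    & (meta["taxon_group"] == "silverfish"),
                    "nest_id",
                ]
            )
        )
        keep = [
            s
            for s in profile.index
            if meta.loc[s, "nest_id"] in focal_nests
            and (
                meta.loc[s, "taxon_group"] == "ant"
                or meta.loc[s, "lifestyle"] == target_style
            )
        ]
        prof = profile.loc[keep]
        nonzero = prof.sum(axis=1) > 0
        dropped = int((~nonzero).sum())
        prof = prof.loc[nonzero]
        if dropped:
            lines.append(
                f"strain profiles: {dropped} sample(s) without any strain dropped"
            )
        prof.to_csv(out / "weissella_profiles.csv")
        results["strain_profiles"] = prof
        if len(prof) >= 6 and prof.shape[1] >= 2:
            jd = pmv.jaccard(prof)
            design = pd.DataFrame(
                {
                    "taxon": meta.loc[prof.index, "taxon_group"].to_numpy(),
                    "nest": meta.loc[prof.index, "nest_id"].to_numpy(),
                },
                index=prof.index,
            )
            for k, order in enumerate(config.term_orders):
                try:
                    res = pmv.permanova_sequential(
                        jd, design, list(order),
                        n_permutations=config.n_permutations,
                        seed=seeds[2 + k],
                    )
                except ValueError as exc:
                    lines.append(
                        f"strain PERMANOVA ({' + '.join(order)}) skipped: {exc}"
                    )
                    continue
                res.table.to_csv(
                    out / f"permanova_weissella_{_slug('_'.join(order))}.csv"
                )
                results[f"weissella_permanova_{order}"] = res
                lines.append(
                    f"Weissella profile order {' + '.join(order)}: "
                    + ", ".join(
                        f"R2[{t}]={res.table.loc[t, 'R2']:.3f}" for t in order
                    )
                )
        else:
            lines.append("strain PERMANOVA skipped: too few profiled samples/strains")

        prev = amp.prevalence(profile, meta, ["taxon_group", "lifestyle"])
        prev.to_csv(out / "weissella_prevalence.csv", index=False)
        results["weissella_prevalence"] = prev

    # 7. endosymbiont prevalence
    ana_cols = [
        z
        for z in counts.columns
        if taxonomy["is_anaplasmataceae"].reindex([z]).fillna(False).iloc[0]
    ]
    if ana_cols:
        pres = (counts.loc[exp_ids, ana_cols] > 0).any(axis=1)
        prev = amp.prevalence(pres, meta, ["taxon_group", "lifestyle"])
        prev.to_csv(out / "anaplasmataceae_prevalence.csv", index=False)
        results["anaplasmataceae_prevalence"] = prev
        lines.append(
            f"Anaplasmataceae infection: {pres.mean():.1%} of experimental samples"
        )

    _write_report(out, "microbiome_report.txt", lines)
    results["report_lines"] = lines
    return results
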