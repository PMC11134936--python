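"""Post-denoising zOTU-table computations.

Starting from an annotated zOTU count table (samples × zOTUs), a
taxonomy map and sample metadata, this module implements the
post-processing chain used for host-associated microbiomes quantified
with a plasmid spike-in:

``relative_abundance`` → ``decontaminate`` (blank-based tenfold rule)
→ ``designate_symbiotic`` → ``subtract_taxon_reads`` (intracellular
endosymbionts) → ``spike_density`` (absolute 16S rRNA copies per ng
DNA) and, in parallel, ``curation_filter`` → ``order_composition`` /
``strain_profile`` / ``prevalence``.

Every filtering function returns (or can return) an audit table so a
run can enumerate exactly which zOTUs were excluded at each stage and
why.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RAMatrix",
    "relative_abundance",
    "decontaminate",
    "designate_symbiotic",
    "subtract_taxon_reads",
    "spike_density",
    "curation_filter",
    "order_composition",
    "strain_profile",
    "prevalence",
]


def _check_counts(counts: pd.DataFrame) -> pd.DataFrame:
    vals = counts.to_numpy()
    if np.any(vals < 0):
        raise ValueError("count table contains negative entries")
    if counts.index.duplicated().any() or counts.columns.duplicated().any():
        raise ValueError("sample or zOTU ids are not unique")
    return counts


def _check_meta(meta: pd.DataFrame, counts: pd.DataFrame) -> pd.DataFrame:
    if "role" not in meta.columns:
        raise ValueError("sample metadata needs a 'role' column")
    missing = counts.index.difference(meta.index)
    if len(missing):
        raise ValueError(f"samples missing from metadata: {list(missing)[:5]}")
    return meta.loc[counts.index]


@dataclass
class RAMatrix:
    """Relative abundances with a record of the denominator basis.

    ``data`` rows sum to 1 over the included zOTUs; ``excluded`` lists
    the zOTU columns left out of the denominator (e.g. the spike-in)
    and ``basis`` is a human-readable note of that choice.
    """

    data: pd.DataFrame
    excluded: list
    basis: str


def relative_abundance(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    exclude_spike: bool = True,
) -> RAMatrix:
    """Per-sample zOTU proportions.

    The spike-in is a known quantification standard, not part of the
    community, so it is excluded from the denominator by default.
    Every sample must retain at least one included read.
    """
    _check_counts(counts)
    excluded = (
        list(taxonomy.index[taxonomy["is_spike_in"].astype(bool)])
        if exclude_spike and "is_spike_in" in taxonomy.columns
        else []
    )
    included = [c for c in counts.columns if c not in excluded]
    sub = counts[included].astype(float)
    totals = sub.sum(axis=1)
    zero = totals == 0
    if zero.any():
        raise ValueError(
            f"sample(s) with zero included reads: {list(counts.index[zero])[:5]}"
        )
    ra = sub.div(totals, axis=0)
    basis = (
        "proportions over non-spike-in zOTUs"
        if excluded
        else "proportions over all zOTUs"
    )
    return RAMatrix(ra, excluded, basis)


def decontaminate(
    ra: RAMatrix, meta: pd.DataFrame, fold: float = 10.0
) -> tuple[list, pd.DataFrame]:
    """Blank-based decontamination with the tenfold rule.

    A zOTU is retained iff its maximum relative abundance in any
    experimental sample is at least ``fold`` times its maximum relative
    abundance in any blank; zOTUs never seen in a blank are always
    retained.  Returns the retained zOTU list and a per-zOTU audit
    table (both maxima, the decision and its reason).
    """
    meta = _check_meta(meta, ra.data)
    blanks = meta.index[meta["role"] == "blank"]
    if len(blanks) == 0:
        raise ValueError(
            "decontamination requires at least one blank sample; none found"
        )
    exp = meta.index[meta["role"] == "experimental"]
    if len(exp) == 0:
        raise ValueError("no experimental samples to decontaminate")
    max_blank = ra.data.loc[blanks].max(axis=0)
    max_exp = ra.data.loc[exp].max(axis=0)
    rows = []
    retained = []
    for z in ra.data.columns:
        mb, me = float(max_blank[z]), float(max_exp[z])
        if mb == 0.0:
            keep, reason = True, "absent from all blanks"
        elif me >= fold * mb:
            keep, reason = True, f"experimental max >= {fold:g}x blank max"
        else:
            keep, reason = False, f"experimental max < {fold:g}x blank max"
        if keep:
            retained.append(z)
        rows.append(
            {
                "zotu": z,
                "max_experimental_ra": me,
                "max_blank_ra": mb,
                "retained": keep,
                "reason": reason,
            }
        )
    return retained, pd.DataFrame(rows).set_index("zotu")


def designate_symbiotic(
    ra: RAMatrix, meta: pd.DataFrame, threshold: float = 0.001
) -> list:
    """zOTUs whose maximum experimental relative abundance is strictly
    above ``threshold`` — the working definition of a symbiotic zOTU."""
    meta = _check_meta(meta, ra.data)
    exp = meta.index[meta["role"] == "experimental"]
    max_exp = ra.data.loc[exp].max(axis=0)
    return [z for z in ra.data.columns if float(max_exp[z]) > threshold]


def subtract_taxon_reads(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    family: str = "Anaplasmataceae",
) -> pd.DataFrame:
    """Drop all zOTU columns belonging to ``family``.

    Intracellular endosymbionts (Anaplasmataceae, notably Wolbachia)
    reach densities that would otherwise swamp the gut-associated
    signal, so their reads are removed before density and composition
    work.  Matching uses the taxonomy's family column and, for the
    default family, the ``is_anaplasmataceae`` flag as well.
    """
    _check_counts(counts)
    tax = taxonomy.reindex(counts.columns)
    mask = tax["family"].fillna("") == family
    if family == "Anaplasmataceae" and "is_anaplasmataceae" in tax.columns:
        mask |= tax["is_anaplasmataceae"].fillna(False).astype(bool)
    return counts.loc[:, ~mask.to_numpy()]


def spike_density(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame,
    spike_copies: float = 1000.0,
    subtract_family: str = "Anaplasmataceae",
    zotus=None,
) -> pd.DataFrame:
    """Absolute symbiont density per experimental sample.

    Converts read counts to 16S rRNA copies using the spike-in standard:

    ``density = ((symbiotic reads − subtracted-family reads) / spike reads)
    × spike_copies / template_ng``

    in copies per ng template DNA.  ``zotus`` optionally restricts the
    symbiotic read total (e.g. to the decontaminated, symbiotic set).
    Samples whose spike-in count is zero get a NaN density and an
    ``undefined`` flag rather than an error.
    """
    _check_counts(counts)
    meta = _check_meta(meta, counts)
    if "is_spike_in" not in taxonomy.columns or not taxonomy["is_spike_in"].any():
        raise ValueError(
            "no spike-in zOTU flagged in the taxonomy; density cannot be computed"
        )
    spike_cols = [
        z for z in counts.columns if taxonomy["is_spike_in"].reindex([z]).fillna(False).iloc[0]
    ]
    if not spike_cols:
        raise ValueError("spike-in zOTU(s) not present in the count table")
    if "template_ng" not in meta.columns:
        raise ValueError("sample metadata needs a 'template_ng' column")

    tax = taxonomy.reindex(counts.columns)
    fam_mask = tax["family"].fillna("") == subtract_family
    if subtract_family == "Anaplasmataceae" and "is_anaplasmataceae" in tax.columns:
        fam_mask |= tax["is_anaplasmataceae"].fillna(False).astype(bool)
    bact_cols = [
        z
        for z in counts.columns
        if z not in spike_cols
        and not fam_mask[z]
        and (zotus is None or z in set(zotus))
    ]
    sub_cols = [z for z in counts.columns if fam_mask[z]]

    exp = meta.index[meta["role"] == "experimental"]
    rows = []
    for sid in exp:
        spike_reads = int(counts.loc[sid, spike_cols].sum())
        sym_reads = int(counts.loc[sid, bact_cols].sum())
        subtracted = int(counts.loc[sid, sub_cols].sum())
        t_ng = float(meta.loc[sid, "template_ng"])
        if not np.isfinite(t_ng) or t_ng <= 0:
            raise ValueError(f"missing or non-positive template_ng for sample {sid}")
        undefined = spike_reads == 0
        density = (
            np.nan
            if undefined
            else (sym_reads / spike_reads) * spike_copies / t_ng
        )
        rows.append(
            {
                "sample_id": sid,
                "symbiotic_reads": sym_reads,
                "spike_reads": spike_reads,
                "subtracted_reads": subtracted,
                "template_ng": t_ng,
                "copies_per_ng": density,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def curation_filter(
    counts: pd.DataFrame,
    mean_threshold: float = 20.0,
    low_variance_fraction: float = 0.10,
) -> tuple[list, pd.DataFrame]:
    """Mean-count and low-variance curation of zOTUs.

    Retains zOTUs whose mean read count across the analysis samples is
    at least ``mean_threshold`` (inclusive) and whose standard
    deviation lies strictly above the ``low_variance_fraction``
    quantile of the SD distribution of the zOTUs that passed the mean
    filter.  Returns the retained list plus an audit table.
    """
    _check_counts(counts)
    if len(counts) < 2:
        raise ValueError("curation needs at least 2 samples")
    means = counts.mean(axis=0)
    sds = counts.std(axis=0, ddof=1)
    pass_mean = means >= mean_threshold
    if not pass_mean.any():
        raise ValueError("every zOTU fails the mean-count filter")
    sd_cut = float(np.quantile(sds[pass_mean].to_numpy(), low_variance_fraction))
    retained = []
    rows = []
    for z in counts.columns:
        ok_mean = bool(pass_mean[z])
        ok_var = bool(sds[z] > sd_cut)
        keep = ok_mean and ok_var
        if keep:
            retained.append(z)
        rows.append(
            {
                "zotu": z,
                "mean_count": float(means[z]),
                "sd_count": float(sds[z]),
                "passed_mean": ok_mean,
                "passed_variance": ok_var,
                "retained": keep,
            }
        )
    if not retained:
        raise ValueError("curation filtered out every zOTU")
    audit = pd.DataFrame(rows).set_index("zotu")
    audit.attrs["sd_cutoff"] = sd_cut
    return retained, audit


def order_composition(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    meta: pd.DataFrame | None = None,
    top_n: int = 9,
    group_by=None,
) -> pd.DataFrame:
    """Order-level community composition with a top-``n`` fold.

    zOTU counts are aggregated to bacterial order; orders are ranked by
    their summed relative abundance across the analysis samples
    (excluding "unassigned"/"Other" from the ranking), the ``top_n``
    most abundant kept, and everything else — including unassigned
    reads — folded into ``Other``.  Rows are proportions that sum to 1.
    With ``group_by`` (e.g. ``["nest_id", "lifestyle"]``) rows are
    averaged per group to avoid pseudo-replication, one row per group.
    """
    _check_counts(counts)
    tax = taxonomy.reindex(counts.columns)
    spike = (
        tax["is_spike_in"].fillna(False).astype(bool)
        if "is_spike_in" in tax.columns
        else pd.Series(False, index=counts.columns)
    )
    use = counts.loc[:, ~spike.to_numpy()]
    orders = tax.loc[use.columns, "order"].fillna("unassigned").replace("", "unassigned")
    agg = use.T.groupby(orders.to_numpy()).sum().T.astype(float)
    totals = agg.sum(axis=1)
    if (totals == 0).any():
        bad = list(agg.index[totals == 0])
        raise ValueError(f"sample(s) with no reads for composition: {bad[:5]}")
    props = agg.div(totals, axis=0)

    rankable = [
        c for c in props.columns if c.lower() not in ("unassigned", "other")
    ]
    ranked = props[rankable].sum(axis=0).sort_values(ascending=False)
    if len(ranked) < top_n:
        import warnings

        warnings.warn(
            f"only {len(ranked)} assigned orders available (< top_n={top_n}); keeping all"
        )
    top = list(ranked.index[:top_n])
    other = [c for c in props.columns if c not in top]
    comp = props[top].copy()
    comp["Other"] = props[other].sum(axis=1)

    if group_by is not None:
        if meta is None:
            raise ValueError("group_by requires sample metadata")
        meta = _check_meta(meta, counts)
        keys = [group_by] if isinstance(group_by, str) else list(group_by)
        comp = comp.join(meta[keys]).groupby(keys).mean()
    return comp


def strain_profile(
    counts: pd.DataFrame,
    taxonomy: pd.DataFrame,
    detection_min_reads: int = 1,
) -> pd.DataFrame:
    """Presence/absence matrix over the flagged target-strain zOTUs.

    A strain counts as present in a sample when its read count is at
    least ``detection_min_reads``.
    """
    _check_counts(counts)
    if "is_weissella_target" not in taxonomy.columns:
        raise ValueError("taxonomy lacks the is_weissella_target flag")
    targets = [
        z
        for z in counts.columns
        if taxonomy["is_weissella_target"].reindex([z]).fillna(False).iloc[0]
    ]
    if not targets:
        raise ValueError("no target strain zOTUs present in the count table")
    return (counts[targets] >= detection_min_reads).astype(int)


def prevalence(
    presence,
    meta: pd.DataFrame,
    grouping="lifestyle",
) -> pd.DataFrame:
    """Per-group fraction of samples carrying at least one target.

    ``presence`` is a binary samples × targets matrix (e.g. a strain
    profile) or a boolean Series per sample.
    """
    if isinstance(presence, pd.DataFrame):
        pos = presence.astype(bool).any(axis=1)
    else:
        pos = pd.Series(presence).astype(bool)
    meta = meta.loc[pos.index]
    keys = [grouping] if isinstance(grouping, str) else list(grouping)
    rows = []
    for key_vals, grp in meta.groupby(keys, sort=True):
        if not isinstance(key_vals, tuple):
            key_vals = (key_vals,)
        rec = dict(zip(keys, key_vals))
        sel = pos.loc[grp.index]
        rec.update(
            {
                "n": len(sel),
                "n_positive": int(sel.sum()),
                "prevalence": float(sel.mean()),
            }
        )
        rows.append(rec)
    return pd.DataFrame(rows)
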