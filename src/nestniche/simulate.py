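"""Synthetic isotope panels and amplicon count tables.

The generator reproduces the statistical structure the downstream
analyses assume, so every stage of the pipeline can be exercised
without field data:

* **Isotopes** — nests draw a baseline isotopic position from a
  between-nest Gaussian; host workers scatter around the baseline with
  individual Gaussian noise, silverfish around baseline plus a taxon
  offset (offset 0 is the fully convergent scenario).
* **Amplicons** — experimental samples carry a plasmid spike-in
  (~1000 copies), gut symbionts with lifestyle-conditional prevalence
  (gamma–Poisson, i.e. negative-binomial reads), intracellular
  Anaplasmataceae endosymbionts, and a per-nest pool of Weissella
  strains shared by ants and silverfish; blanks carry reagent
  contaminants that leak into experimental samples well below the
  tenfold decontamination bar.

All randomness flows from a single seed through one NumPy generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "IsotopeSimConfig",
    "AmpliconSimConfig",
    "ContaminantProfile",
    "SymbiontProfile",
    "gen_isotope_panel",
    "gen_amplicon_panel",
    "load_config",
]


@dataclass
class IsotopeSimConfig:
    """Parameters of the nest-structured isotope simulation.

    Defaults mirror a Mediterranean granivorous-ant study design:
    12 colonies, 6 workers and 4 silverfish measured per colony,
    baselines near δ13C = −26 ‰ / δ15N = 5.5 ‰, strong between-colony
    spread in δ15N and modest individual noise.
    """

    n_nests: int = 12
    workers_per_nest: int = 6
    silverfish_per_nest: int = 4
    baseline_mean_c: float = -26.0
    baseline_mean_n: float = 5.5
    nest_sd_c: float = 0.6
    nest_sd_n: float = 1.5
    ind_sd_c: float = 0.4
    ind_sd_n: float = 0.5
    taxon_offset_c: float = 0.0
    taxon_offset_n: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nests", "workers_per_nest", "silverfish_per_nest"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("nest_sd_c", "nest_sd_n", "ind_sd_c", "ind_sd_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_isotope_panel(config: IsotopeSimConfig) -> pd.DataFrame:
    """Simulate a specimen-level isotope panel (one row per specimen)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_nests):
        nest = f"N{i + 1:02d}"
        base_c = rng.normal(config.baseline_mean_c, config.nest_sd_c)
        base_n = rng.normal(config.baseline_mean_n, config.nest_sd_n)
        for j in range(config.workers_per_nest):
            rows.append(
                {
                    "sample_id": f"{nest}_ant{j + 1}",
                    "species": "Messor_host",
                    "taxon_group": "ant",
                    "lifestyle": "host",
                    "nest_id": nest,
                    "d13C": base_c + rng.normal(0.0, config.ind_sd_c),
                    "d15N": base_n + rng.normal(0.0, config.ind_sd_n),
                }
            )
        for j in range(config.silverfish_per_nest):
            rows.append(
                {
                    "sample_id": f"{nest}_sf{j + 1}",
                    "species": "Neoasterolepisma_specialist",
                    "taxon_group": "silverfish",
                    "lifestyle": "Messor-specialized",
                    "nest_id": nest,
                    "d13C": base_c
                    + config.taxon_offset_c
                    + rng.normal(0.0, config.ind_sd_c),
                    "d15N": base_n
                    + config.taxon_offset_n
                    + rng.normal(0.0, config.ind_sd_n),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Amplicon simulation
# ---------------------------------------------------------------------------


@dataclass
class ContaminantProfile:
    """A reagent contaminant and its relative-abundance level in blanks."""

    zotu: str
    blank_level: float
    order: str = "unassigned"
    family: str = "unassigned"
    genus: str = "unassigned"

    def __post_init__(self) -> None:
        if not (0.0 <= self.blank_level):
            raise ValueError("blank_level must be >= 0")


@dataclass
class SymbiontProfile:
    """A gut-symbiont zOTU with lifestyle-conditional prevalence.

    ``prevalence`` may be a scalar or a mapping whose keys are tried in
    the order ``"{taxon}:{lifestyle}"``, ``"{taxon}"``, ``"default"``.
    ``mean_copies`` is the mean 16S rRNA copy number in a reaction when
    the symbiont is present; copy numbers are gamma-distributed with
    the given dispersion, so read counts are negative-binomial.
    """

    zotu: str
    order: str
    family: str
    genus: str
    prevalence: float | dict = 0.5
    mean_copies: float = 2000.0
    dispersion: float = 0.5

    def prob(self, taxon: str, lifestyle: str) -> float:
        if isinstance(self.prevalence, dict):
            for key in (f"{taxon}:{lifestyle}", taxon, "default"):
                if key in self.prevalence:
                    return float(self.prevalence[key])
            return 0.0
        return float(self.prevalence)


def _default_contaminants() -> list[ContaminantProfile]:
    return [
        ContaminantProfile(
            "zotu_cont_ralstonia", 0.5, "Burkholderiales", "Burkholderiaceae", "Ralstonia"
        ),
        ContaminantProfile(
            "zotu_cont_sphingo", 0.3, "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas"
        ),
        ContaminantProfile(
            "zotu_cont_cuti", 0.2, "Propionibacteriales", "Propionibacteriaceae", "Cutibacterium"
        ),
    ]


def _default_symbionts() -> list[SymbiontProfile]:
    return [
        SymbiontProfile(
            "zotu_lacto4",
            "Lactobacillales",
            "Lactobacillaceae",
            "unassigned",
            {"silverfish:Messor-specialized": 0.77, "ant": 0.07, "default": 0.0},
            8000.0,
        ),
        SymbiontProfile(
            "zotu_strep1", "Lactobacillales", "Streptococcaceae", "Streptococcus", 0.4, 3000.0
        ),
        SymbiontProfile(
            "zotu_entb1", "Enterobacterales", "Enterobacteriaceae", "Enterobacter", 0.5, 5000.0
        ),
        SymbiontProfile(
            "zotu_entb2", "Enterobacterales", "Enterobacteriaceae", "unassigned", 0.3, 2000.0
        ),
        SymbiontProfile(
            "zotu_spiro1",
            "Entomoplasmatales",
            "Spiroplasmataceae",
            "Spiroplasma",
            {"silverfish": 0.2, "ant": 0.05},
            6000.0,
        ),
        SymbiontProfile(
            "zotu_rick1", "Rickettsiales", "Rickettsiaceae", "Rickettsia", 0.15, 5000.0
        ),
        SymbiontProfile(
            "zotu_card1", "Cytophagales", "Amoebophilaceae", "Cardinium", 0.1, 7000.0
        ),
        SymbiontProfile(
            "zotu_rckl1",
            "Diplorickettsiales",
            "Diplorickettsiaceae",
            "Rickettsiella",
            0.1,
            4000.0,
        ),
        SymbiontProfile(
            "zotu_pseu1", "Pseudomonadales", "Pseudomonadaceae", "Pseudomonas", 0.5, 2000.0
        ),
        SymbiontProfile(
            "zotu_baci1", "Bacillales", "Bacillaceae", "Bacillus", 0.4, 1500.0
        ),
        SymbiontProfile(
            "zotu_xant1",
            "Xanthomonadales",
            "Xanthomonadaceae",
            "Stenotrophomonas",
            0.3,
            1200.0,
        ),
        # ubiquitous low-level environmental background: every specimen
        # carries a detectable microbiome
        SymbiontProfile(
            "zotu_unas1", "unassigned", "unassigned", "unassigned", 1.0, 1000.0
        ),
    ]


@dataclass
class AmpliconSimConfig:
    """Parameters of the amplicon count-table simulation.

    The default design is 12 nests (half hosting Messor-specialized
    silverfish, a quarter each Aphaenogaster-specialized and obligate
    generalist), 2 ants and 3 silverfish sequenced per nest, and 9
    blank samples (emulating six extraction plus three PCR blanks).
    ``spike_copies`` plasmid copies of the quantification standard are
    added to every reaction; ``spike_mean_reads`` sets the expected
    read yield of those copies.  Each Messor nest shares a pool of
    ``strains_per_nest`` Weissella strains (out of ``weissella_pool_size``)
    between its ants and silverfish; ``detection_noise`` is the
    per-strain false-negative probability.
    """

    n_nests: int = 12
    ants_per_nest: int = 2
    silverfish_per_nest: int = 3
    n_blanks: int = 9
    spike_mean_reads: float = 1000.0
    spike_copies: float = 1000.0
    template_ng_range: tuple[float, float] = (5.0, 20.0)
    contaminant_profiles: list[ContaminantProfile] = field(
        default_factory=_default_contaminants
    )
    blank_total_reads: float = 2000.0
    leakage_factor: float = 0.2
    symbiont_profiles: list[SymbiontProfile] = field(default_factory=_default_symbionts)
    anaplasmataceae_prevalence: float = 0.36
    anaplasmataceae_mean_copies: float = 20000.0
    weissella_pool_size: int = 18
    strains_per_nest: int = 6
    weissella_mean_copies: float = 500.0
    detection_noise: float = 0.05
    nest_lifestyles: dict = field(
        default_factory=lambda: {
            "Messor-specialized": 0.5,
            "Aphaenogaster-specialized": 0.25,
            "obligate generalist": 0.25,
        }
    )
    read_yield_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_nests", "ants_per_nest", "silverfish_per_nest"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be >= 1")
        for p in ("anaplasmataceae_prevalence", "detection_noise"):
            if not (0.0 <= getattr(self, p) <= 1.0):
                raise ValueError(f"{p} must lie in [0, 1]")
        if self.spike_copies <= 0:
            raise ValueError("spike_copies must be > 0")
        if self.spike_mean_reads < 0 or self.weissella_mean_copies < 0:
            raise ValueError("read/copy levels must be >= 0")
        if self.strains_per_nest > self.weissella_pool_size:
            raise ValueError("strains_per_nest cannot exceed weissella_pool_size")
        if self.n_blanks == 0 and self.contaminant_profiles:
            raise ValueError(
                "contaminant profiles requested but n_blanks is 0; the "
                "decontamination rule would be untestable"
            )
        lo, hi = self.template_ng_range
        if not (0 < lo <= hi):
            raise ValueError("template_ng_range must be a positive interval")


# host ant genus used for each silverfish lifestyle
_HOST_OF = {
    "Messor-specialized": "Messor",
    "Aphaenogaster-specialized": "Aphaenogaster",
    "obligate generalist": "Camponotus",
}


def _nest_lifestyle_assignment(config: AmpliconSimConfig) -> list[str]:
    """Deterministic nest -> silverfish-lifestyle assignment by quota."""
    styles = list(config.nest_lifestyles)
    weights = np.array([config.nest_lifestyles[s] for s in styles], dtype=float)
    weights = weights / weights.sum()
    quota = np.floor(weights * config.n_nests).astype(int)
    while quota.sum() < config.n_nests:
        quota[int(np.argmax(weights * config.n_nests - quota))] += 1
    out: list[str] = []
    for s, q in zip(styles, quota):
        out.extend([s] * int(q))
    return out[: config.n_nests]


def gen_amplicon_panel(
    config: AmpliconSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate (CountTable, TaxonomyMap, SampleMeta).

    Returns
    -------
    counts:
        samples × zOTUs integer read counts.
    taxonomy:
        per-zOTU order/family/genus and the ``is_spike_in``,
        ``is_anaplasmataceae`` and ``is_weissella_target`` flags.
    meta:
        per-sample role, taxon group, species, lifestyle, nest, template
        DNA mass (ng) and the generator's ground-truth symbiotic density
        ``true_copies_per_ng`` (NaN for blanks).
    """
    rng = np.random.default_rng(config.seed)

    weissella = [f"zotu_weissella{i + 1:02d}" for i in range(config.weissella_pool_size)]
    anaplasma = ["zotu_wolbachia_a", "zotu_wolbachia_b"]
    zotus = (
        ["zotu_spike_ec5502"]
        + [c.zotu for c in config.contaminant_profiles]
        + [s.zotu for s in config.symbiont_profiles]
        + anaplasma
        + weissella
    )
    if len(set(zotus)) != len(zotus):
        raise ValueError("duplicate zOTU ids across profiles")

    tax_rows = [
        {
            "zotu": "zotu_spike_ec5502",
            "order": "",
            "family": "",
            "genus": "",
            "is_spike_in": True,
            "is_anaplasmataceae": False,
            "is_weissella_target": False,
        }
    ]
    for c in config.contaminant_profiles:
        tax_rows.append(
            {
                "zotu": c.zotu,
                "order": c.order,
                "family": c.family,
                "genus": c.genus,
                "is_spike_in": False,
                "is_anaplasmataceae": False,
                "is_weissella_target": False,
            }
        )
    for s in config.symbiont_profiles:
        tax_rows.append(
            {
                "zotu": s.zotu,
                "order": s.order,
                "family": s.family,
                "genus": s.genus,
                "is_spike_in": False,
                "is_anaplasmataceae": False,
                "is_weissella_target": False,
            }
        )
    for z in anaplasma:
        tax_rows.append(
            {
                "zotu": z,
                "order": "Rickettsiales",
                "family": "Anaplasmataceae",
                "genus": "Wolbachia",
                "is_spike_in": False,
                "is_anaplasmataceae": True,
                "is_weissella_target": False,
            }
        )
    for z in weissella:
        tax_rows.append(
            {
                "zotu": z,
                "order": "Lactobacillales",
                "family": "Lactobacillaceae",
                "genus": "Weissella",
                "is_spike_in": False,
                "is_anaplasmataceae": False,
                "is_weissella_target": True,
            }
        )
    taxonomy = pd.DataFrame(tax_rows).set_index("zotu")

    lifestyles = _nest_lifestyle_assignment(config)
    nest_strains: dict[str, list[str]] = {}
    cont_levels = np.array([c.blank_level for c in config.contaminant_profiles])
    cont_hat = cont_levels / cont_levels.sum() if cont_levels.size else cont_levels

    count_rows: dict[str, dict[str, int]] = {}
    meta_rows = []

    def _gamma(mean: float, disp: float) -> float:
        shape = 1.0 / max(disp, 1e-9)
        return float(rng.gamma(shape, mean / shape))

    for i in range(config.n_nests):
        nest = f"N{i + 1:02d}"
        style = lifestyles[i]
        host_genus = _HOST_OF.get(style, "Messor")
        if style == "Messor-specialized":
            nest_strains[nest] = sorted(
                rng.choice(weissella, size=config.strains_per_nest, replace=False)
            )
        else:
            nest_strains[nest] = []
        members = [(f"{nest}_ant{j + 1}", "ant") for j in range(config.ants_per_nest)]
        members += [
            (f"{nest}_sf{j + 1}", "silverfish")
            for j in range(config.silverfish_per_nest)
        ]
        for sid, taxon in members:
            lifestyle = "host" if taxon == "ant" else style
            species = (
                f"{host_genus}_host"
                if taxon == "ant"
                else f"Neoasterolepisma_{style.split('-')[0].replace(' ', '_')}"
            )
            t_ng = float(rng.uniform(*config.template_ng_range))
            ryield = (config.spike_mean_reads / config.spike_copies) * float(
                np.exp(rng.normal(0.0, config.read_yield_sd))
            )
            copies: dict[str, float] = {}
            for prof in config.symbiont_profiles:
                if rng.random() < prof.prob(taxon, lifestyle):
                    copies[prof.zotu] = _gamma(prof.mean_copies, prof.dispersion)
            if rng.random() < config.anaplasmataceae_prevalence:
                genotype = anaplasma[int(rng.integers(len(anaplasma)))]
                copies[genotype] = _gamma(config.anaplasmataceae_mean_copies, 0.5)
            for strain in nest_strains[nest]:
                if rng.random() >= config.detection_noise:
                    copies[strain] = _gamma(config.weissella_mean_copies, 0.5)

            reads = {
                z: int(rng.poisson(ryield * c)) for z, c in copies.items()
            }
            reads["zotu_spike_ec5502"] = int(
                rng.poisson(ryield * config.spike_copies)
            )
            non_cont_total = sum(
                r for z, r in reads.items() if z != "zotu_spike_ec5502"
            )
            for c, lv in zip(config.contaminant_profiles, cont_hat):
                lam = config.leakage_factor * lv * non_cont_total
                reads[c.zotu] = int(rng.poisson(lam))
            true_sym = sum(
                c
                for z, c in copies.items()
                if z not in anaplasma  # truth excludes intracellular endosymbionts
            )
            count_rows[sid] = reads
            meta_rows.append(
                {
                    "sample_id": sid,
                    "role": "experimental",
                    "taxon_group": taxon,
                    "species": species,
                    "lifestyle": lifestyle,
                    "nest_id": nest,
                    "template_ng": t_ng,
                    "true_copies_per_ng": true_sym / t_ng,
                }
            )

    for b in range(config.n_blanks):
        sid = f"blank{b + 1}"
        reads = {
            "zotu_spike_ec5502": int(rng.poisson(config.spike_mean_reads))
        }
        for c, lv in zip(config.contaminant_profiles, cont_hat):
            reads[c.zotu] = int(rng.poisson(lv * config.blank_total_reads))
        count_rows[sid] = reads
        meta_rows.append(
            {
                "sample_id": sid,
                "role": "blank",
                "taxon_group": "n/a",
                "species": "",
                "lifestyle": "",
                "nest_id": "",
                "template_ng": np.nan,
                "true_copies_per_ng": np.nan,
            }
        )

    counts = (
        pd.DataFrame.from_dict(count_rows, orient="index")
        .reindex(columns=zotus)
        .fillna(0)
        .astype(int)
    )
    counts.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return counts, taxonomy, meta


# ---------------------------------------------------------------------------
# Config files
# ---------------------------------------------------------------------------


def load_config(path, kind: str):
    """Load an ``IsotopeSimConfig`` or ``AmpliconSimConfig`` from YAML/JSON.

    ``kind`` is ``"isotope"`` or ``"amplicon"``.  Contaminant and
    symbiont profiles may be given as lists of mappings mirroring the
    dataclass fields; omitted fields fall back to the defaults.
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} does not hold a mapping")
    if kind == "isotope":
        return IsotopeSimConfig(**data)
    if kind != "amplicon":
        raise ValueError("kind must be 'isotope' or 'amplicon'")
    if "contaminant_profiles" in data:
        data["contaminant_profiles"] = [
            ContaminantProfile(**c) for c in data["contaminant_profiles"]
        ]
    if "symbiont_profiles" in data:
        data["symbiont_profiles"] = [
            SymbiontProfile(**s) for s in data["symbiont_profiles"]
        ]
    if "template_ng_range" in data:
        data["template_ng_range"] = tuple(data["template_ng_range"])
    return AmpliconSimConfig(**data)


def config_to_dict(config) -> dict:
    """Plain-dict view of a simulation config (for logging/round-trip)."""
    return asdict(config)
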