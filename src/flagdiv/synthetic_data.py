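"""Synthetic flagellin panels with ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* conserved N/C-terminal domains (190 and 100 aa) with hierarchical
  divergence — a global consensus, phylum-level ancestors, species-level
  ancestors, and per-sequence substitutions;
* a middle variable region partitioned into mutually non-alignable HVR
  *forms* (independent uniform-random ancestors per form) containing
  SNP-level *isoforms*;
* FlgL-like decoys that carry both conserved domains (drawn from a
  separate FlgL clade) around a shuffled middle, so they pass the domain
  filter and must be removed by the discriminant;
* archaeal records built on a single unrelated conserved domain;
* unrelated random decoys; and duplicate observations of the same unique
  sequence via a multiplicity distribution.

Every record has exactly one truth row (category, phylum, species,
cluster lineage, form, isoform, region boundaries), so curation,
clustering, HVR typing and diversity can each be scored against truth.
All randomness flows from one seed through numpy SeedSequence spawning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from . import hvr_typing
from .curation import (ARCH_FLAG, FLAG_C, FLAG_N, FLAGELLIN_DISCRIM,
                       FLGL_DISCRIM, AA_ORDER, DomainModel)
from .sequence_model import SequenceRecord, TaxonomyLabel

_AA = np.array(list(AA_ORDER))

_CODONS_BY_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_BY_AA.setdefault(_aa, []).append(_codon)
for _v in _CODONS_BY_AA.values():
    _v.sort()


@dataclass
class PanelConfig:
    """Study conditions of the synthetic corpus.

    Divergence parameters are per-position substitution probabilities:
    ``phylum_divergence`` separates cluster lineages (low cross-lineage
    identity), ``species_divergence`` plus ``eps_c`` give within-lineage
    conserved variation, ``eps_v`` is the within-form SNP rate defining
    isoforms.  Defaults keep within-form identity above 0.9 and cross-form
    identity below the alignability threshold, the dual-level separation
    the typing scheme relies on.
    """

    rng_seed: int = 0
    n_phyla: int = 3
    species_per_phylum: int = 1
    forms_per_species: int = 26
    isoform_choices: tuple[int, ...] = (1, 2, 3)
    conserved5_len: int = 190
    conserved3_len: int = 100
    variable_len_range: tuple[int, int] = (130, 200)
    phylum_divergence: float = 0.40
    species_divergence: float = 0.05
    eps_c: float = 0.02
    eps_v: float = 0.02
    flgl_divergence: float = 0.30
    n_flgl_decoys: int = 8
    n_archaeal_species: int = 2
    archaeal_forms_per_species: int = 1
    archaeal_isoform_choices: tuple[int, ...] = (2, 3, 4)
    archaeal_domain_len: int = 150
    n_random_decoys: int = 8
    multiplicity_choices: tuple[int, ...] = (1, 1, 2, 3)
    n_hgt_species: int = 1
    verify_separation: bool = True
    max_regeneration: int = 20

    def __post_init__(self) -> None:
        if self.forms_per_species < 1:
            raise ValueError("forms_per_species must be >= 1")
        if not (0 <= self.eps_v < 0.5 and 0 <= self.eps_c < 0.5):
            raise ValueError("substitution rates must be in [0, 0.5)")
        if self.conserved5_len <= 0 or self.conserved3_len <= 0:
            raise ValueError("conserved lengths must be positive")
        if self.variable_len_range[0] > self.variable_len_range[1]:
            raise ValueError("variable_len_range must be (lo, hi) with lo <= hi")
        if self.n_hgt_species > 0 and self.n_phyla < 2:
            raise ValueError("HGT species require at least 2 phyla")


@dataclass
class Panel:
    """Generated records plus truth table and matching domain models."""

    proteins: list[SequenceRecord]
    cds: list[SequenceRecord]
    truth: pd.DataFrame
    models: list[DomainModel]
    config: PanelConfig
    regenerations: int = 0

    def taxonomy_map(self) -> dict[str, TaxonomyLabel]:
        return {rec.id: rec.taxonomy for rec in self.proteins}


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_AA, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        choices = [a for a in AA_ORDER if a != out[i]]
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def _cds_for(rng: np.random.Generator, protein: str) -> str:
    """Codon-consistent CDS: a random synonymous codon per residue, no stop."""
    parts = []
    for aa in protein:
        codons = _CODONS_BY_AA[aa if aa != "X" else "A"]
        parts.append(codons[int(rng.integers(len(codons)))])
    return "".join(parts)


def _nonalignable_ancestors(rng: np.random.Generator, n: int,
                            len_range: tuple[int, int],
                            verify: bool, max_regen: int) -> tuple[list[str], int]:
    """Draw n mutually non-alignable variable-region ancestors.

    Uniform-random regions are non-alignable with overwhelming probability;
    when ``verify`` is set each new ancestor is checked against the
    accepted ones with the typing predicate and redrawn on a collision
    (the regeneration count is reported).
    """
    ancestors: list[str] = []
    regen = 0
    while len(ancestors) < n:
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        cand = _random_protein(rng, length)
        if verify and any(hvr_typing.alignable(cand, a) for a in ancestors):
            regen += 1
            if regen > max_regen:
                raise RuntimeError("could not draw non-alignable ancestors")
            continue
        ancestors.append(cand)
    return ancestors, regen


def generate_panel(config: PanelConfig | None = None) -> Panel:
    """Generate the full synthetic panel, truth table and domain models.

    Deterministic in ``config.rng_seed``: the same seed yields
    byte-identical sequences, ids and truth rows.
    """
    config = config or PanelConfig()
    root = np.random.SeedSequence(config.rng_seed)
    (ss_consensus, ss_phyla, ss_forms, ss_members, ss_decoys,
     ss_arch, ss_mult) = root.spawn(7)
    rng_cons = np.random.default_rng(ss_consensus)
    rng_phy = np.random.default_rng(ss_phyla)
    rng_forms = np.random.default_rng(ss_forms)
    rng_mem = np.random.default_rng(ss_members)
    rng_dec = np.random.default_rng(ss_decoys)
    rng_arch = np.random.default_rng(ss_arch)
    rng_mult = np.random.default_rng(ss_mult)

    consensus_n = _random_protein(rng_cons, config.conserved5_len)
    consensus_c = _random_protein(rng_cons, config.conserved3_len)
    arch_consensus = _random_protein(rng_cons, config.archaeal_domain_len)

    # cluster lineages = phylum-level conserved ancestors
    lineage_n: dict[str, str] = {}
    lineage_c: dict[str, str] = {}
    phyla = [f"Phylum{p + 1:02d}" for p in range(config.n_phyla)]
    for ph in phyla:
        lineage_n[ph] = _mutate(rng_phy, consensus_n, config.phylum_divergence)
        lineage_c[ph] = _mutate(rng_phy, consensus_c, config.phylum_divergence)

    flgl_anc_n = _mutate(rng_phy, consensus_n, config.flgl_divergence)
    flgl_anc_c = _mutate(rng_phy, consensus_c, config.flgl_divergence)

    arch_phylum = "ArchPhylum01"
    arch_species_doms = [
        _mutate(rng_phy, arch_consensus, config.species_divergence)
        for _ in range(config.n_archaeal_species)
    ]

    proteins: list[SequenceRecord] = []
    cds: list[SequenceRecord] = []
    rows: list[dict] = []
    counter = 0
    regenerations = 0

    def emit(protein: str, dna: str | None, tax: TaxonomyLabel,
             **truth) -> None:
        nonlocal counter
        mult = int(rng_mult.choice(config.multiplicity_choices))
        for _ in range(mult):
            counter += 1
            rid = f"seq{counter:05d}"
            proteins.append(SequenceRecord(id=rid, residues=protein,
                                           kind="protein", taxonomy=tax))
            if dna is not None:
                cds.append(SequenceRecord(id=rid, residues=dna, kind="dna",
                                          taxonomy=tax))
            rows.append({"record_id": rid,
                         "superkingdom": tax.superkingdom,
                         "phylum": tax.phylum, "species": tax.species,
                         **truth})

    # --- bacterial flagellins -------------------------------------------
    species_index = 0
    for pi, ph in enumerate(phyla):
        for si in range(config.species_per_phylum):
            species_index += 1
            sp = f"{ph}_sp{si + 1}"
            # an HGT species keeps its own phylum label but carries the
            # conserved lineage of the previous phylum -> multi-phylum cluster
            is_hgt = (pi >= config.n_phyla - config.n_hgt_species
                      and si == config.species_per_phylum - 1
                      and config.n_phyla >= 2)
            lineage_ph = phyla[(pi - 1) % config.n_phyla] if is_hgt else ph
            sp_n = _mutate(rng_mem, lineage_n[lineage_ph],
                           config.species_divergence)
            sp_c = _mutate(rng_mem, lineage_c[lineage_ph],
                           config.species_divergence)
            ancestors, regen = _nonalignable_ancestors(
                rng_forms, config.forms_per_species, config.variable_len_range,
                config.verify_separation, config.max_regeneration)
            regenerations += regen
            tax = TaxonomyLabel(superkingdom="Bacteria", phylum=ph,
                                genus=ph, species=sp)
            for fi, anc in enumerate(ancestors, start=1):
                form = f"{sp}_F{fi:02d}"
                n_iso = int(rng_mem.choice(config.isoform_choices))
                iso_ids: dict[str, str] = {}  # distinct variable string -> id
                for ii in range(1, n_iso + 1):
                    var = anc if ii == 1 else _mutate(rng_mem, anc, config.eps_v)
                    iso = iso_ids.setdefault(var, f"{form}.{len(iso_ids) + 1}")
                    prot = (_mutate(rng_mem, sp_n, config.eps_c) + var
                            + _mutate(rng_mem, sp_c, config.eps_c))
                    dna = _cds_for(rng_mem, prot)
                    emit(prot, dna, tax, category="flagellin",
                         lineage=f"lineage_{lineage_ph}",
                         form_id=form, isoform_id=iso,
                         var_start=config.conserved5_len,
                         var_end=config.conserved5_len + len(var))

    # --- archaeal flagellins (single conserved domain) ------------------
    for si in range(config.n_archaeal_species):
        sp = f"{arch_phylum}_sp{si + 1}"
        sp_dom = arch_species_doms[si]
        ancestors, regen = _nonalignable_ancestors(
            rng_arch, config.archaeal_forms_per_species,
            config.variable_len_range, config.verify_separation,
            config.max_regeneration)
        regenerations += regen
        tax = TaxonomyLabel(superkingdom="Archaea", phylum=arch_phylum,
                            genus=arch_phylum, species=sp)
        for fi, anc in enumerate(ancestors, start=1):
            form = f"{sp}_F{fi:02d}"
            n_iso = int(rng_arch.choice(config.archaeal_isoform_choices))
            iso_ids: dict[str, str] = {}
            for ii in range(1, n_iso + 1):
                var = anc if ii == 1 else _mutate(rng_arch, anc, config.eps_v)
                iso = iso_ids.setdefault(var, f"{form}.{len(iso_ids) + 1}")
                prot = _mutate(rng_arch, sp_dom, config.eps_c) + var
                # single conserved domain: the lineage (cluster family) is
                # the species, since only the domain aligns across species
                emit(prot, _cds_for(rng_arch, prot), tax, category="archaeal",
                     lineage=f"lineage_{sp}",
                     form_id=form, isoform_id=iso,
                     var_start=config.archaeal_domain_len,
                     var_end=config.archaeal_domain_len + len(var))

    # --- FlgL-like decoys: both conserved domains, shuffled middle ------
    flgl_tax = TaxonomyLabel(superkingdom="Bacteria", phylum=phyla[0],
                             species="FlgL_like")
    for di in range(config.n_flgl_decoys):
        mid_len = int(rng_dec.integers(*config.variable_len_range))
        mid = _random_protein(rng_dec, mid_len)
        prot = (_mutate(rng_dec, flgl_anc_n, config.eps_c) + mid
                + _mutate(rng_dec, flgl_anc_c, config.eps_c))
        emit(prot, None, flgl_tax, category="flgl_decoy", lineage="lineage_FlgL",
             form_id="", isoform_id="", var_start=-1, var_end=-1)

    # --- unrelated random decoys ----------------------------------------
    for di in range(config.n_random_decoys):
        length = int(rng_dec.integers(300, 501))
        prot = _random_protein(rng_dec, length)
        emit(prot, None, TaxonomyLabel(), category="random", lineage="",
             form_id="", isoform_id="", var_start=-1, var_end=-1)

    truth = pd.DataFrame(rows)

    # --- domain models trained on the ancestral seed sets ----------------
    phylum_n = [lineage_n[ph] for ph in phyla]
    phylum_c = [lineage_c[ph] for ph in phyla]
    models = [
        DomainModel.from_sequences(FLAG_N, phylum_n + [flgl_anc_n],
                                   expected_terminus="N"),
        DomainModel.from_sequences(FLAG_C, phylum_c + [flgl_anc_c],
                                   expected_terminus="C"),
        DomainModel.from_sequences(ARCH_FLAG, arch_species_doms,
                                   expected_terminus="N"),
        DomainModel.from_sequences(FLAGELLIN_DISCRIM, phylum_n),
        DomainModel.from_sequences(FLGL_DISCRIM, [flgl_anc_n]),
    ]
    return Panel(proteins=proteins, cds=cds, truth=truth, models=models,
                 config=config, regenerations=regenerations)


def generate_counts_table(n_phyla: int = 40, slope: float = 0.93,
                          intercept: float = -0.2, noise_sd: float = 0.05,
                          rng_seed: int = 0,
                          log_total_range: tuple[float, float] = (1.5, 5.0)
                          ) -> pd.DataFrame:
    """Per-phylum (n_total, n_unique) counts with a known log-log law.

    log10 n_unique = intercept + slope * log10 n_total + Normal(0, noise_sd),
    rounded and clipped to [1, n_total]; n_total is log-uniform over the
    configured range.  Emulates the near-linear unique-vs-total
    relationship the diversity regression measures.
    """
    if not 0 < slope <= 1:
        raise ValueError("slope must be in (0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(rng_seed)
    log_t = rng.uniform(*log_total_range, size=n_phyla)
    n_total = np.maximum(np.round(10.0 ** log_t).astype(int), 2)
    log_u = intercept + slope * np.log10(n_total) + rng.normal(0, noise_sd,
                                                               size=n_phyla)
    n_unique = np.clip(np.round(10.0 ** log_u).astype(int), 1, n_total)
    return pd.DataFrame({
        "taxon": [f"Phylum{i + 1:02d}" for i in range(n_phyla)],
        "n_total": n_total,
        "n_unique": n_unique,
    })


def generate_selection_panel(rng_seed: int = 0, n_seqs: int = 8,
                             variable_len: int = 150,
                             conserved5_len: int = 190,
                             conserved3_len: int = 100,
                             syn_rate: float = 0.10,
                             var_snp_rate: float = 0.10
                             ) -> list[SequenceRecord]:
    """CDS panel for the selection curves: a reference plus mutants whose
    terminal regions carry only synonymous codon changes and whose middle
    carries unconstrained nucleotide SNPs.

    Mirrors an H-antigen gene set: purifying selection on the conserved
    termini (synonymous variation only) and diversity in the variable
    region.
    """
    rng = np.random.default_rng(rng_seed)
    protein = _random_protein(rng, conserved5_len + variable_len + conserved3_len)
    ref_cds = _cds_for(rng, protein)
    lo = 3 * conserved5_len
    hi = 3 * (conserved5_len + variable_len)
    records = [SequenceRecord(id="ref00", residues=ref_cds, kind="dna")]
    for k in range(1, n_seqs):
        codons = [ref_cds[i:i + 3] for i in range(0, len(ref_cds), 3)]
        for ci, codon in enumerate(codons):
            start = 3 * ci
            in_variable = lo <= start < hi
            if in_variable:
                if rng.random() < var_snp_rate:
                    pos = int(rng.integers(3))
                    base = "ACGT"[int(rng.integers(4))]
                    cand = codon[:pos] + base + codon[pos + 1:]
                    if cand not in standard_dna_table.stop_codons:
                        codons[ci] = cand
            else:
                if rng.random() < syn_rate:
                    aa = standard_dna_table.forward_table[codon]
                    alts = [c for c in _CODONS_BY_AA[aa] if c != codon]
                    if alts:
                        codons[ci] = alts[int(rng.integers(len(alts)))]
        records.append(SequenceRecord(id=f"mut{k:02d}", residues="".join(codons),
                                      kind="dna"))
    return records
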