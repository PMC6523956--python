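"""Synthetic annotated genomes with planted, machine-readable ground
truth, plus codon-pair and qPCR simulators.

The genome generator emulates the data regime of a genome-wide
gene-family survey: multi-chromosome gene orders; a planted family whose
members share a 79-aa HMG-like core domain plus group-diagnostic motifs;
duplicate pairs arranged to realise each MCScanX class (tandem =
adjacent ranks, proximal = nearby ranks, dispersed = far apart,
WGD/segmental = inside a planted collinear run of homologous gene
pairs); and anchor pairs with a chosen number of conserved flanking
homologs for microsynteny.  Every planted entity is recorded in a
:class:`SimTruth` table so downstream modules can be scored at
precision = recall = 1.

Design notes
------------
* Background proteins are drawn with uniform amino-acid composition and
  length 200-600, enough to make E-value gates meaningful.
* Duplicate-pair partners are produced by *codon-level* evolution of the
  source CDS under a controlled dN/dS (see :func:`evolve_cds`), so the
  pipeline's Ka/Ks stage sees pairs with a known omega.
* Singleton planting is not supported: family members share the
  diagnostic domain by definition, so every member has a significant
  family homolog and the singleton class is structurally empty for a
  domain-defined family (surveys of such families indeed report zero
  singletons).  The classifier still implements the singleton branch
  for genes without homologs.
* Group references are derived hierarchically: a single random 79-aa
  core is mutated at ~10% of sites per group to give group reference
  domains, and each member's domain mutates its group reference at ~4%
  of sites.  This keeps within-family identity comfortably above the
  70% group rule while making "nearest reference" group assignment
  well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import (
    CdsRecord,
    GeneModel,
    ProteinRecord,
    write_cds_fasta,
    write_gff3,
    write_protein_fasta,
)

__all__ = [
    "SimConfig",
    "SimTruth",
    "SimulatedGenome",
    "simulate_genome",
    "simulate_codon_pair",
    "evolve_cds",
    "simulate_ct_table",
    "write_dataset",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NT = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}

# standard genetic code, laid out here to keep the simulator self-contained
_CODONS = [a + b + c for a in _NT for b in _NT for c in _NT]
from Bio.Data.CodonTable import unambiguous_dna_by_id as _tables

_AA_OF = dict(_tables[1].forward_table)
_SENSE = sorted(_AA_OF)
_CODONS_OF_AA: dict[str, list[str]] = {}
for _c, _a in _AA_OF.items():
    _CODONS_OF_AA.setdefault(_a, []).append(_c)
for _a in _CODONS_OF_AA:
    _CODONS_OF_AA[_a].sort()

DOMAIN_LENGTH = 79
MOTIF_LENGTH = 12
DEFAULT_GROUPS = ("B1", "B2", "C", "D", "E", "F", "H")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a synthetic genome.

    Defaults emulate a galliform-like survey: 18 family members in seven
    groups over a dozen chromosomes, with two tandem, two proximal, two
    WGD/segmental and twelve dispersed members, and two planted
    microsynteny blocks carrying 3 and 2 conserved flanking pairs.
    """

    n_chromosomes: int = 12
    genes_per_chromosome: int = 26
    n_family_members: int = 18
    planted_duplications: Mapping[str, int] = field(
        default_factory=lambda: {
            "tandem": 2, "proximal": 2, "wgd_segmental": 2, "dispersed": 12,
        }
    )
    planted_blocks: tuple[int, ...] = (3, 2)  # conserved flankers per block
    omega_targets: tuple[float, ...] = (0.2,)
    divergence_t: float = 0.1  # expected substitutions per codon for pairs
    n_domain_ablated: int = 1  # negative controls with the domain scrambled
    groups: tuple[str, ...] = DEFAULT_GROUPS
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_chromosomes, self.genes_per_chromosome,
               self.n_family_members) <= 0:
            raise ValueError("counts must be positive")
        if any(w <= 0 for w in self.omega_targets):
            raise ValueError("omega targets must be positive")
        dup = dict(self.planted_duplications)
        if dup.get("singleton", 0) > 0:
            raise ValueError(
                "singleton family members cannot be planted: members share "
                "the diagnostic domain, so every member has a family homolog"
            )
        for cls, n in dup.items():
            if cls not in {"tandem", "proximal", "wgd_segmental", "dispersed",
                           "singleton"}:
                raise ValueError(f"unknown duplication class {cls!r}")
            if n < 0 or (cls != "dispersed" and n % 2):
                raise ValueError(f"{cls} count must be a non-negative even number")
        if sum(dup.values()) != self.n_family_members:
            raise ValueError(
                "planted duplication counts must sum to n_family_members"
            )
        if dup.get("dispersed", 0) < 2 * len(self.planted_blocks):
            raise ValueError(
                "each planted microsynteny block consumes two dispersed anchors"
            )
        if self.genes_per_chromosome < 22:
            raise ValueError(
                "genes_per_chromosome < 22 cannot host the planted layouts"
            )


@dataclass
class SimTruth:
    """Planted ground truth emitted with every synthetic genome."""

    family_gene_ids: list[str]
    group_of: dict[str, str]
    dup_class_of: dict[str, str]
    true_blocks: list[dict]  # {"anchor_a", "anchor_b", "n_conserved"}
    true_omega: dict[str, float]  # "geneA|geneB" -> omega
    ablated_gene_ids: list[str]

    def omega_of(self, a: str, b: str) -> float | None:
        return self.true_omega.get("|".join(sorted((a, b))))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        with open(path, encoding="utf-8") as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedGenome:
    config: SimConfig
    genes: list[GeneModel]
    proteins: list[ProteinRecord]
    cds: list[CdsRecord]
    seeds: list[ProteinRecord]  # group reference proteins (mining seeds)
    references: dict[str, str]  # group label -> reference domain sequence
    truth: SimTruth


# ---------------------------------------------------------------------------
# sequence-level helpers


from .physchem import KYTE_DOOLITTLE as _KD

# residue weights favouring hydrophilic composition; planted family
# proteins use these for their non-domain parts, emulating the uniformly
# hydrophilic (GRAVY < 0) character of HMG-box transcription factors
_HYDRO_W = np.array([np.exp(-_KD[a] / 2.5) for a in AMINO_ACIDS])
_HYDRO_W /= _HYDRO_W.sum()


def _random_protein(
    rng: np.random.Generator, length: int, hydrophilic: bool = False
) -> str:
    p = _HYDRO_W if hydrophilic else None
    return "".join(rng.choice(list(AMINO_ACIDS), size=length, p=p))


def _mutate_protein(rng: np.random.Generator, seq: str, n_sites: int) -> str:
    """Substitute ``n_sites`` distinct positions with different residues."""
    chars = list(seq)
    positions = rng.choice(len(chars), size=min(n_sites, len(chars)),
                           replace=False)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != chars[pos]]
        chars[pos] = alternatives[rng.integers(len(alternatives))]
    return "".join(chars)


def _back_translate(rng: np.random.Generator, protein: str,
                    add_stop: bool = True) -> str:
    codons = [
        _CODONS_OF_AA[aa][rng.integers(len(_CODONS_OF_AA[aa]))]
        for aa in protein
    ]
    if add_stop:
        codons.append("TAA")
    return "".join(codons)


def _translate(cds: str) -> str:
    seq = cds[:-3] if cds[-3:] in _STOPS else cds
    return "".join(_AA_OF[seq[i:i + 3]] for i in range(0, len(seq), 3))


def evolve_cds(
    cds: str,
    omega: float,
    t: float,
    rng: np.random.Generator,
) -> tuple[str, int, int]:
    """Evolve a stop-free coding sequence under a controlled dN/dS.

    Substitution events are Poisson with mean ``t`` per codon.  Each
    event proposes a uniform single-nucleotide change (any position, any
    of its 3 alternatives — the same kernel the NG86 site counting
    assumes); proposals creating stop codons are rejected outright, and
    nonsynonymous proposals are accepted with probability proportional
    to ``omega`` relative to synonymous ones.  Returns the descendant
    and the realized (synonymous, nonsynonymous) substitution counts.
    """
    if omega <= 0 and t > 0:
        p_syn, p_nonsyn = 1.0, 0.0
    elif omega <= 1.0:
        p_syn, p_nonsyn = 1.0, omega
    else:
        p_syn, p_nonsyn = 1.0 / omega, 1.0
    has_stop_suffix = cds[-3:] in _STOPS
    body = cds[:-3] if has_stop_suffix else cds
    if len(body) % 3:
        raise ValueError("CDS length not divisible by 3")
    codons = [body[i:i + 3] for i in range(0, len(body), 3)]
    n_events = int(rng.poisson(t * len(codons)))
    syn = nonsyn = 0
    guard = 0
    while (syn + nonsyn) < n_events:
        guard += 1
        if guard > 1000 * (n_events + 1):
            raise RuntimeError("substitution sampler failed to accept")
        ci = int(rng.integers(len(codons)))
        pos = int(rng.integers(3))
        cur = codons[ci]
        alternatives = [nt for nt in _NT if nt != cur[pos]]
        alt_nt = alternatives[int(rng.integers(3))]
        cand = cur[:pos] + alt_nt + cur[pos + 1:]
        if cand in _STOPS:
            continue
        synonymous = _AA_OF[cand] == _AA_OF[cur]
        accept_p = p_syn if synonymous else p_nonsyn
        if accept_p < 1.0 and rng.random() >= accept_p:
            continue
        codons[ci] = cand
        if synonymous:
            syn += 1
        else:
            nonsyn += 1
    out = "".join(codons) + (cds[-3:] if has_stop_suffix else "")
    return out, syn, nonsyn


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    t: float,
    seed: int,
) -> tuple[CdsRecord, CdsRecord, dict[str, int]]:
    """An ancestral/descendant coding pair diverged under dN/dS = omega.

    The ancestor is drawn uniformly over sense codons; the descendant is
    produced by :func:`evolve_cds`.  Realized substitution counts are
    returned as the third element.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = "".join(_SENSE[i] for i in rng.integers(len(_SENSE),
                                                       size=n_codons))
    descendant, syn, nonsyn = evolve_cds(ancestor, omega, t, rng)
    return (
        CdsRecord("ancestor", ancestor),
        CdsRecord("descendant", descendant),
        {"synonymous": syn, "nonsynonymous": nonsyn},
    )


# ---------------------------------------------------------------------------
# genome layout planning

_BLOCK_OFFSETS = (-6, -3, 4, 7, -9, 10, -12, 13, -15, 16)


@dataclass
class _Placement:
    chrom: int
    rank: int
    kind: str  # family | bg_pair | ablated
    label: str


def _plan_layout(cfg: SimConfig) -> dict:
    """Deterministic placement of every planted entity.

    Fresh chromosomes are consumed per entity so that planted flanking
    homologs can never leak into another anchor's window; the remaining
    chromosomes hold only background genes.
    """
    gpc = cfg.genes_per_chromosome
    dup = dict(cfg.planted_duplications)
    cursor = 0

    def fresh_chrom() -> int:
        nonlocal cursor
        if cursor >= cfg.n_chromosomes:
            raise ValueError(
                "infeasible layout: planted entities need more chromosomes "
                f"than the configured {cfg.n_chromosomes}"
            )
        cursor += 1
        return cursor - 1

    members: list[dict] = []  # chrom, rank, class, pair_id
    bg_pairs: list[dict] = []  # (chrom, rank) x2 source/partner
    blocks: list[dict] = []
    pair_id = 0

    for _ in range(dup.get("tandem", 0) // 2):
        c = fresh_chrom()
        r = gpc // 3
        members.append({"chrom": c, "rank": r, "class": "tandem", "pair": pair_id})
        members.append({"chrom": c, "rank": r + 1, "class": "tandem", "pair": pair_id})
        pair_id += 1
    for _ in range(dup.get("proximal", 0) // 2):
        c = fresh_chrom()
        r = gpc // 4
        members.append({"chrom": c, "rank": r, "class": "proximal", "pair": pair_id})
        members.append({"chrom": c, "rank": r + 3, "class": "proximal", "pair": pair_id})
        pair_id += 1
    for _ in range(dup.get("wgd_segmental", 0) // 2):
        ca, cb = fresh_chrom(), fresh_chrom()
        center_a, center_b = gpc // 2 - 3, gpc // 2
        members.append({"chrom": ca, "rank": center_a, "class": "wgd_segmental",
                        "pair": pair_id})
        members.append({"chrom": cb, "rank": center_b, "class": "wgd_segmental",
                        "pair": pair_id})
        for off in (-3, -2, -1, 1, 2, 3):
            bg_pairs.append({
                "a": (ca, center_a + off), "b": (cb, center_b + off),
            })
        blocks.append({"pair": pair_id, "n_conserved": 6, "segmental": True})
        pair_id += 1

    n_dispersed = dup.get("dispersed", 0)
    for n_flank in cfg.planted_blocks:
        if n_flank > len(_BLOCK_OFFSETS):
            raise ValueError("too many conserved flankers requested per block")
        ca, cb = fresh_chrom(), fresh_chrom()
        ra, rb = gpc // 3, gpc - 6
        offsets = _BLOCK_OFFSETS[:n_flank]
        for off in offsets:
            if not (0 <= ra + off < gpc and 0 <= rb + off < gpc):
                raise ValueError("infeasible layout: flanker offset out of range")
            if abs(off) > 20:
                raise ValueError("flanker offset beyond the 20-gene window")
        members.append({"chrom": ca, "rank": ra, "class": "dispersed",
                        "pair": pair_id})
        members.append({"chrom": cb, "rank": rb, "class": "dispersed",
                        "pair": pair_id})
        for off in offsets:
            bg_pairs.append({"a": (ca, ra + off), "b": (cb, rb + off)})
        blocks.append({"pair": pair_id, "n_conserved": n_flank,
                       "segmental": False})
        n_dispersed -= 2
        pair_id += 1

    # dispersed singles, two per fresh chromosome (far apart)
    lo, hi = 5, gpc - 2
    while n_dispersed > 0:
        c = fresh_chrom()
        members.append({"chrom": c, "rank": lo, "class": "dispersed",
                        "pair": None})
        n_dispersed -= 1
        if n_dispersed > 0:
            members.append({"chrom": c, "rank": hi, "class": "dispersed",
                            "pair": None})
            n_dispersed -= 1

    ablated: list[tuple[int, int]] = []
    occupied = {(m["chrom"], m["rank"]) for m in members}
    occupied |= {p["a"] for p in bg_pairs} | {p["b"] for p in bg_pairs}
    for i in range(cfg.n_domain_ablated):
        slot = (0, gpc - 3 - i)
        if slot in occupied or slot[1] < 0:
            raise ValueError("infeasible layout: no slot for ablated control")
        ablated.append(slot)
        occupied.add(slot)

    return {"members": members, "bg_pairs": bg_pairs, "blocks": blocks,
            "ablated": ablated}


# ---------------------------------------------------------------------------
# genome emission


def simulate_genome(config: SimConfig) -> SimulatedGenome:
    """Emit an annotated synthetic genome with its planted truth table."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    gpc = config.genes_per_chromosome
    layout = _plan_layout(config)

    # family scaffolding: core domain, per-group references, seed proteins
    core = _random_protein(rng, DOMAIN_LENGTH)
    references: dict[str, str] = {}
    motifs: dict[str, str] = {}
    ref_flanks: dict[str, tuple[str, str]] = {}
    for group in config.groups:
        references[group] = _mutate_protein(rng, core, 8)  # ~10% of 79
        motifs[group] = _random_protein(rng, MOTIF_LENGTH)
        ref_flanks[group] = (_random_protein(rng, 120), _random_protein(rng, 120))
    seeds = [
        ProteinRecord(
            f"seed_{group}", f"seed_{group}",
            ref_flanks[group][0] + motifs[group] + references[group]
            + ref_flanks[group][1],
        )
        for group in config.groups
    ]

    # assign groups: pair entities first, then singles, cycling the list
    members = layout["members"]
    pair_ids = sorted({m["pair"] for m in members if m["pair"] is not None})
    group_cycle = list(config.groups)
    group_of_pair = {
        pid: group_cycle[i % len(group_cycle)] for i, pid in enumerate(pair_ids)
    }
    singles = [m for m in members if m["pair"] is None]
    for i, m in enumerate(singles):
        m["group"] = group_cycle[(len(pair_ids) + i) % len(group_cycle)]
    for m in members:
        if m["pair"] is not None:
            m["group"] = group_of_pair[m["pair"]]

    def gene_id(chrom: int, rank: int) -> str:
        return f"chr{chrom + 1:02d}g{rank:03d}"

    def member_protein(group: str) -> str:
        nf = _random_protein(rng, int(rng.integers(80, 200)), hydrophilic=True)
        cf = _random_protein(rng, int(rng.integers(80, 200)), hydrophilic=True)
        domain = _mutate_protein(rng, references[group], 3)  # ~4% of 79
        return nf + motifs[group] + domain + cf

    # build sequences for planted entities
    prot_of: dict[tuple[int, int], str] = {}
    cds_of: dict[tuple[int, int], str] = {}
    truth_group: dict[str, str] = {}
    truth_class: dict[str, str] = {}
    truth_omega: dict[str, float] = {}

    by_pair: dict[int, list[dict]] = {}
    for m in members:
        if m["pair"] is not None:
            by_pair.setdefault(m["pair"], []).append(m)

    omega_cycle = list(config.omega_targets)
    for i, pid in enumerate(pair_ids):
        a, b = sorted(by_pair[pid], key=lambda m: (m["chrom"], m["rank"]))
        omega = omega_cycle[i % len(omega_cycle)]
        prot_a = member_protein(a["group"])
        cds_a = _back_translate(rng, prot_a)
        cds_b, _, _ = evolve_cds(cds_a, omega, config.divergence_t, rng)
        prot_b = _translate(cds_b)
        for m, prot, cds in ((a, prot_a, cds_a), (b, prot_b, cds_b)):
            key = (m["chrom"], m["rank"])
            prot_of[key], cds_of[key] = prot, cds
            gid = gene_id(*key)
            truth_group[gid] = m["group"]
            truth_class[gid] = m["class"]
        truth_omega["|".join(sorted((gene_id(a["chrom"], a["rank"]),
                                     gene_id(b["chrom"], b["rank"]))))] = omega
    for m in singles:
        key = (m["chrom"], m["rank"])
        prot = member_protein(m["group"])
        prot_of[key] = prot
        cds_of[key] = _back_translate(rng, prot)
        gid = gene_id(*key)
        truth_group[gid] = m["group"]
        truth_class[gid] = m["class"]

    # background homolog pairs (collinear segments, conserved flankers)
    for bp in layout["bg_pairs"]:
        length = int(rng.integers(200, 601))
        src = _random_protein(rng, length)
        partner = _mutate_protein(rng, src, max(1, length // 50))  # ~2%
        prot_of[bp["a"]] = src
        prot_of[bp["b"]] = partner
        cds_of[bp["a"]] = _back_translate(rng, src)
        cds_of[bp["b"]] = _back_translate(rng, partner)

    # ablated negative controls: a reference protein with the domain
    # scrambled — found by seed search, rejected by the domain scan
    ablated_ids: list[str] = []
    for i, slot in enumerate(layout["ablated"]):
        group = group_cycle[i % len(group_cycle)]
        nf, cf = ref_flanks[group]
        prot = nf + motifs[group] + _random_protein(rng, DOMAIN_LENGTH) + cf
        prot_of[slot] = prot
        cds_of[slot] = _back_translate(rng, prot)
        ablated_ids.append(gene_id(*slot))

    # background genes everywhere else
    genes: list[GeneModel] = []
    proteins: list[ProteinRecord] = []
    cds_records: list[CdsRecord] = []
    for c in range(config.n_chromosomes):
        for r in range(gpc):
            key = (c, r)
            if key not in prot_of:
                prot = _random_protein(rng, int(rng.integers(200, 601)))
                prot_of[key] = prot
                cds_of[key] = _back_translate(rng, prot)
            gid = gene_id(c, r)
            start = 1 + r * 4000
            end = start + len(cds_of[key]) - 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneModel(gid, f"chr{c + 1:02d}", start, end,
                                   strand, rank=r))
            proteins.append(ProteinRecord(f"{gid}.p1", gid, prot_of[key]))
            cds_records.append(CdsRecord(gid, cds_of[key]))

    true_blocks = []
    for blk in layout["blocks"]:
        a, b = sorted(by_pair[blk["pair"]], key=lambda m: (m["chrom"], m["rank"]))
        true_blocks.append({
            "anchor_a": gene_id(a["chrom"], a["rank"]),
            "anchor_b": gene_id(b["chrom"], b["rank"]),
            "n_conserved": blk["n_conserved"],
        })
    truth = SimTruth(
        family_gene_ids=sorted(truth_class),
        group_of=truth_group,
        dup_class_of=truth_class,
        true_blocks=sorted(true_blocks,
                           key=lambda d: (d["anchor_a"], d["anchor_b"])),
        true_omega=truth_omega,
        ablated_gene_ids=ablated_ids,
    )
    return SimulatedGenome(config, genes, proteins, cds_records, seeds,
                           references, truth)


def write_dataset(sim: SimulatedGenome, outdir: str | Path) -> dict[str, Path]:
    """Write GFF3 + FASTA + seed/reference files + truth sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gff3": outdir / "genes.gff3",
        "proteins": outdir / "proteins.faa",
        "cds": outdir / "cds.fna",
        "seeds": outdir / "seeds.faa",
        "references": outdir / "reference_domains.faa",
        "truth_json": outdir / "truth.json",
        "truth_tsv": outdir / "truth_members.tsv",
    }
    write_gff3(sim.genes, paths["gff3"])
    write_protein_fasta(sim.proteins, paths["proteins"])
    write_cds_fasta(sim.cds, paths["cds"])
    write_protein_fasta(sim.seeds, paths["seeds"])
    write_protein_fasta(
        [ProteinRecord(g, g, seq) for g, seq in sim.references.items()],
        paths["references"],
    )
    sim.truth.to_json(paths["truth_json"])
    pd.DataFrame(
        {
            "gene_id": sim.truth.family_gene_ids,
            "group": [sim.truth.group_of[g] for g in sim.truth.family_gene_ids],
            "dup_class": [sim.truth.dup_class_of[g]
                          for g in sim.truth.family_gene_ids],
        }
    ).to_csv(paths["truth_tsv"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# qPCR tables


def simulate_ct_table(
    genes: Sequence[str],
    conditions: Sequence[str],
    true_fold_changes: Mapping[tuple[str, str], float],
    noise_sd: float,
    seed: int,
    reference_gene: str = "beta_actin",
    n_biological: int = 3,
    n_technical: int = 3,
) -> pd.DataFrame:
    """Triplicate CT tables whose 2^-ddCT expectation equals the
    requested fold changes.

    ``true_fold_changes`` maps (gene, condition) to the fold change
    relative to the first condition (the calibrator); missing entries
    default to 1.  A per-sample plate offset shared by every gene in a
    sample is included, which the ddCT estimator must cancel.
    """
    if reference_gene in genes:
        raise ValueError("reference gene is added automatically")
    rng = np.random.default_rng(seed)
    calibrator = conditions[0]
    rows = []
    for condition in conditions:
        for bio in range(1, n_biological + 1):
            plate = float(rng.normal(0.0, 0.5))
            for gene in [reference_gene, *genes]:
                if gene == reference_gene:
                    base = 16.0
                else:
                    fold = float(true_fold_changes.get((gene, condition), 1.0))
                    base_cal = float(true_fold_changes.get((gene, calibrator), 1.0))
                    # CT drops by one cycle per doubling of expression
                    base = 22.0 - np.log2(fold / base_cal)
                for tech in range(1, n_technical + 1):
                    noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
                    rows.append(
                        {
                            "gene": gene,
                            "condition": condition,
                            "biological_replicate": bio,
                            "technical_replicate": tech,
                            "ct": base + plate + noise,
                        }
                    )
    return pd.DataFrame(rows)
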