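"""Synthetic index-sorted germinal-center datasets with recorded ground truth.

Generates everything the analysis pipeline consumes — an in-frame V-gene
template with CDR annotations, per-gate cell populations carrying mutated
sequences, index-sort tables, Sanger per-cell FASTA files, bulk NGS FASTQ
read sets with enrichment sorting and sub-threshold sequencing-error
contaminants — so the whole pipeline is testable end to end without any
external data.

Two generation modes:

* ``"prescribed"`` — each cell's stop status is Bernoulli(gate truth) and a
  matching sequence is constructed (a stop-creating substitution or a
  frameshifting deletion at a random eligible site, on top of stop-free
  background mutations).  Gate truths are exact by construction, which is
  what recovery tests need.
* ``"mechanistic"`` — sequences come from the SHM simulator and the stop
  frequencies are whatever emerge, which is what model validation needs.

Scenario presets carry the frequencies measured in index-sorted mouse
germinal centers (wild-type DZ 4.6% vs LZ 1.3%; DZ BCR-high 2.2% vs
BCR-low 17.2%; Bcl2-transgenic DZ 11.6%, BCR-low 25.0%, LZ 0.8%) as
generator parameters.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calling import SampleReads
from .expectation import snapshot_division_distribution
from .gating import GatingTree, GateNode
from .simulate import SimConfig, simulate_cohort
from .template import (
    BASES,
    STOP_CODONS,
    DEFAULT_MOTIF_PATTERNS,
    RegionPartition,
    VGeneTemplate,
    find_hotspot_motifs,
    partition_regions,
)

__all__ = [
    "GateSpec",
    "SequencingSpec",
    "ScenarioConfig",
    "ScenarioData",
    "PRESETS",
    "preset_config",
    "generate_template",
    "generate_population",
    "generate_scenario",
    "write_scenario",
]

NON_STOP_CODONS = tuple(
    a + b + c
    for a in BASES for b in BASES for c in BASES
    if a + b + c not in STOP_CODONS
)


@dataclass
class GateSpec:
    """One gate of the synthetic gating tree.

    ``truth`` (prescribed stop frequency, as a fraction) and ``enrichment``
    (sorting oversampling factor) apply to leaves only.
    """

    name: str
    parent: str | None = None
    fraction_of_parent: float = 1.0
    truth: float | None = None
    enrichment: float = 1.0
    channel_bcr: float | None = None
    channel_cxcr4: float | None = None


@dataclass
class SequencingSpec:
    """How cells are sampled and read out.

    ``budget`` maps a parent gate to the number of cells sequenced from
    beneath it; cells are allocated to its leaves proportionally to
    pre-enrichment fraction times enrichment factor.  Sanger reads are
    error-free; NGS reads carry per-base substitution errors and each sample
    additionally receives ``contaminants_per_sample`` unique error sequences
    at ``contaminant_cells_worth`` of a cell's expected read count (kept
    below the (100/n)% abundance threshold).
    """

    budget: dict = field(default_factory=dict)
    reads_per_cell_mean: float = 50.0
    reads_per_cell_dispersion: float = 5.0
    error_rate: float = 0.0
    contaminants_per_sample: int = 0
    contaminant_cells_worth: float = 0.3
    emit_sanger: bool = True
    emit_ngs: bool = False


@dataclass
class ScenarioConfig:
    name: str = "custom"
    template_codons: int = 131
    cdr_fraction: float = 0.2
    motif_patterns: tuple = DEFAULT_MOTIF_PATTERNS
    gates: list = field(default_factory=list)
    mode: str = "prescribed"            # "prescribed" | "mechanistic"
    max_divisions: int = 2              # snapshot D for division draws
    mu: float = 1e-3
    p_del: float = 0.006
    frameshift_share: float = 0.138     # share of prescribed stops that are frameshifts
    divisions_by_gate: dict = field(default_factory=dict)  # mechanistic overrides
    sequencing: SequencingSpec = field(default_factory=SequencingSpec)

    def __post_init__(self):
        if self.mode not in ("prescribed", "mechanistic"):
            raise ValueError("mode must be 'prescribed' or 'mechanistic'")
        if self.mode == "mechanistic":
            for g in self.gates:
                if g.truth is not None:
                    raise ValueError(
                        f"gate {g.name}: prescribed truth conflicts with mechanistic mode"
                    )


def _wildtype_gates() -> list[GateSpec]:
    return [
        GateSpec("GC"),
        GateSpec("DZ", "GC", 0.55),
        GateSpec("LZ", "GC", 0.35),
        GateSpec("CXCR4low_CD83low", "GC", 0.10, truth=0.010,
                 channel_bcr=3.0, channel_cxcr4=2.0),
        GateSpec("DZ_BCRhigh", "DZ", 0.84, truth=0.022,
                 channel_bcr=3.0, channel_cxcr4=3.5),
        GateSpec("DZ_BCRlow", "DZ", 0.16, truth=0.172, enrichment=10.0,
                 channel_bcr=1.0, channel_cxcr4=3.5),
        GateSpec("LZ_BCRhigh", "LZ", 0.90, truth=0.014,
                 channel_bcr=3.0, channel_cxcr4=2.0),
        GateSpec("LZ_BCRlow", "LZ", 0.10, truth=0.004, enrichment=10.0,
                 channel_bcr=1.0, channel_cxcr4=2.0),
    ]


def _preset_wildtype() -> ScenarioConfig:
    # DZ rollup: 0.84*2.2% + 0.16*17.2% = 4.6%; LZ: 0.9*1.4% + 0.1*0.4% = 1.3%
    return ScenarioConfig(
        name="wildtype",
        gates=_wildtype_gates(),
        sequencing=SequencingSpec(
            budget={"DZ": 500, "LZ": 500, "CXCR4low_CD83low": 60},
            emit_sanger=True, emit_ngs=True,
            contaminants_per_sample=3, error_rate=0.0,
        ),
    )


def _preset_wildtype_dz_split() -> ScenarioConfig:
    gates = [
        GateSpec("DZ"),
        GateSpec("DZ_BCRhigh", "DZ", 0.84, truth=0.022,
                 channel_bcr=3.0, channel_cxcr4=3.5),
        GateSpec("DZ_BCRlow", "DZ", 0.16, truth=0.172, enrichment=10.0,
                 channel_bcr=1.0, channel_cxcr4=3.5),
    ]
    return ScenarioConfig(
        name="wildtype-dz-split", gates=gates,
        sequencing=SequencingSpec(budget={"DZ": 500}, emit_sanger=True),
    )


def _preset_bcl2() -> ScenarioConfig:
    # DZ rollup: 0.7*5.857% + 0.3*25.0% = 11.6%
    gates = [
        GateSpec("GC"),
        GateSpec("DZ", "GC", 0.60),
        GateSpec("LZ", "GC", 0.30),
        GateSpec("CXCR4low_CD83low", "GC", 0.10, truth=0.010,
                 channel_bcr=3.0, channel_cxcr4=2.0),
        GateSpec("DZ_BCRhigh", "DZ", 0.70, truth=0.058571,
                 channel_bcr=3.0, channel_cxcr4=3.5),
        GateSpec("DZ_BCRlow", "DZ", 0.30, truth=0.250, enrichment=5.0,
                 channel_bcr=1.0, channel_cxcr4=3.5),
        GateSpec("LZ_all", "LZ", 1.0, truth=0.008,
                 channel_bcr=3.0, channel_cxcr4=2.0),
    ]
    return ScenarioConfig(
        name="bcl2", gates=gates,
        sequencing=SequencingSpec(
            budget={"DZ": 500, "LZ": 300, "CXCR4low_CD83low": 60},
            emit_sanger=True,
        ),
    )


PRESETS = {
    "wildtype": _preset_wildtype,
    "wildtype-dz-split": _preset_wildtype_dz_split,
    "bcl2": _preset_bcl2,
}


def preset_config(name: str) -> ScenarioConfig:
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return PRESETS[name]()


# ---------------------------------------------------------------------------
# template generation
# ---------------------------------------------------------------------------

def generate_template(n_codons: int = 131, cdr_fraction: float = 0.2,
                      rng: np.random.Generator | int = 0,
                      template_id: str = "synthetic_vgene",
                      target_q: float | None = None) -> VGeneTemplate:
    """Random in-frame template with no internal stops and three CDR blocks.

    The default 131 codons (393 nt) matches the length of a typical
    rearranged heavy-chain V region.  CDR blocks sit at fixed relative
    positions (mimicking CDR1/2/3) and together cover about ``cdr_fraction``
    of the gene.

    ``target_q`` tunes the codon composition so that the unweighted
    per-mutation stop probability of the stand-in matches a specified value
    (a real V gene's q is a fixed property of its sequence; a typical
    heavy-chain V region sits near 0.06).  The achievable resolution is
    1/(9 * n_codons).
    """
    if n_codons < 10:
        raise ValueError("n_codons must be >= 10")
    if not (0.0 <= cdr_fraction <= 0.8):
        raise ValueError("cdr_fraction must be in [0, 0.8]")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    codons = list(rng.choice(NON_STOP_CODONS, size=n_codons))
    if target_q is not None:
        codons = _tune_codon_risk(codons, target_q, rng)
    seq = "".join(codons)
    cdrs: list[tuple[int, int]] = []
    if cdr_fraction > 0:
        n_cdr_codons = max(3, round(cdr_fraction * n_codons))
        block = max(1, n_cdr_codons // 3)
        for anchor in (0.20, 0.45, 0.75):
            start_codon = int(anchor * n_codons)
            end_codon = min(n_codons, start_codon + block)
            cdrs.append((3 * start_codon, 3 * end_codon))
    return VGeneTemplate(template_id, seq, tuple(cdrs))


def _tune_codon_risk(codons: list, target_q: float,
                     rng: np.random.Generator) -> list:
    """Swap codons until the summed stop-risk count matches ``target_q``.

    The unweighted per-mutation stop probability is (sum of codon risk
    counts) / (9 * n_codons), so hitting a target reduces to integer
    bookkeeping over risk-count classes.
    """
    from .template import codon_stop_risk

    risk_of = {c: codon_stop_risk(c)[0] for c in NON_STOP_CODONS}
    by_risk = {k: [c for c, r in risk_of.items() if r == k] for k in (0, 1, 2)}
    target_total = round(target_q * 9 * len(codons))
    if target_total > 2 * len(codons):
        raise ValueError(f"target_q {target_q} unreachable for {len(codons)} codons")
    total = sum(risk_of[c] for c in codons)
    for _ in range(100 * len(codons)):
        if total == target_total:
            break
        i = int(rng.integers(0, len(codons)))
        k = risk_of[codons[i]]
        if total > target_total and k > 0:
            new_k = k - 1
        elif total < target_total and k < 2:
            new_k = k + 1
        else:
            continue
        pool = by_risk[new_k]
        codons[i] = pool[int(rng.integers(0, len(pool)))]
        total += new_k - k
    else:
        raise RuntimeError("codon-risk tuning did not converge")
    return codons


# ---------------------------------------------------------------------------
# population generation
# ---------------------------------------------------------------------------

def _weighted_position(rng: np.random.Generator, weights: np.ndarray) -> int:
    return int(rng.choice(len(weights), p=weights))


def _apply_nonstop_substitution(seq: list[str], rng: np.random.Generator,
                                pweights: np.ndarray, max_tries: int = 100) -> None:
    """One substitution that does not create a stop codon (rejection sampled)."""
    for _ in range(max_tries):
        i = _weighted_position(rng, pweights)
        old = seq[i]
        new = BASES[int(rng.integers(0, 4))]
        if new == old:
            continue
        cs = 3 * (i // 3)
        codon = "".join(seq[cs:cs + 3])
        mutated = codon[:i - cs] + new + codon[i - cs + 1:]
        if mutated not in STOP_CODONS:
            seq[i] = new
            return
    raise RuntimeError("could not place a stop-free substitution")


def _stop_creating_sites(seq: Sequence[str]) -> list[tuple[int, str]]:
    """All (position, base) substitutions that turn a codon into a stop."""
    sites = []
    for cs in range(0, len(seq) - 2, 3):
        codon = "".join(seq[cs:cs + 3])
        if codon in STOP_CODONS:
            continue
        for off in range(3):
            for base in BASES:
                if base == codon[off]:
                    continue
                if codon[:off] + base + codon[off + 1:] in STOP_CODONS:
                    sites.append((cs + off, base))
    return sites


def _prescribed_sequence(template: VGeneTemplate, pweights: np.ndarray,
                         rng: np.random.Generator, divisions: int, p_m: float,
                         want_stop: bool, frameshift_share: float,
                         ) -> tuple[str, bool, bool]:
    """Build one cell sequence with a known stop status.

    Returns (sequence, has_stop, has_frameshift); ``has_stop or
    has_frameshift`` equals ``want_stop`` by construction.
    """
    seq = list(template.seq)
    n_background = int(rng.binomial(divisions, min(1.0, p_m))) if divisions > 0 else 0
    for _ in range(n_background):
        _apply_nonstop_substitution(seq, rng, pweights)
    if not want_stop:
        return "".join(seq), False, False
    if rng.random() < frameshift_share:
        from .simulate import translate_has_premature_stop
        length = int(rng.integers(1, 3))  # 1 or 2 nt: always frame-breaking
        i = int(rng.integers(0, len(seq) - length))
        del seq[i:i + length]
        # the shifted downstream frame usually contains incidental stops;
        # record the same in-frame-translation flag the classifier reports
        return "".join(seq), translate_has_premature_stop("".join(seq)), True
    sites = _stop_creating_sites(seq)
    pos, base = sites[int(rng.integers(0, len(sites)))]
    seq[pos] = base
    return "".join(seq), True, False


def _allocate(budget: int, leaves: list[GateSpec]) -> dict[str, int]:
    """Split a parent's sequencing budget over its leaves proportionally to
    pre-enrichment fraction x enrichment factor (every leaf gets >= 1)."""
    raw = np.array([g.fraction_of_parent * g.enrichment for g in leaves], dtype=float)
    shares = raw / raw.sum() * budget
    counts = np.maximum(1, np.round(shares).astype(int))
    return {g.name: int(c) for g, c in zip(leaves, counts)}


@dataclass
class ScenarioData:
    """Everything one synthetic run produced, plus its ground truth."""

    config: ScenarioConfig
    seed: int
    template: VGeneTemplate
    partition: RegionPartition
    tree: GatingTree
    cells: pd.DataFrame                  # cell_id, gate, divisions, has_stop, has_frameshift, seq
    index_table: pd.DataFrame            # cell_id, gate, channel_bcr, channel_cxcr4
    sanger_samples: dict                 # gate -> SampleReads (one per cell)
    ngs_samples: dict                    # gate -> SampleReads (bulk reads)
    contaminant_ids: dict                # gate -> list of contaminant sequence ids
    ground_truth: dict


def generate_population(config: ScenarioConfig, template: VGeneTemplate,
                        partition: RegionPartition,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Generate the sequenced cells for every leaf gate.

    The number of cells per leaf reflects the sorting enrichment (rare gates
    oversampled); the gate's pre-enrichment fraction lives in the tree and is
    what the rollup corrects with.
    """
    pweights = np.asarray(partition.position_weights(), dtype=float)
    pweights = pweights / pweights.sum()
    p_m = template.length * config.mu
    dist = snapshot_division_distribution(config.max_divisions)
    ks = sorted(dist.probs)
    ps = np.array([dist.probs[k] for k in ks])

    by_name = {g.name: g for g in config.gates}
    leaf_names = {g.name for g in config.gates
                  if not any(h.parent == g.name for h in config.gates)}
    rows = []
    for parent, budget in sorted(config.sequencing.budget.items()):
        leaves = [g for g in config.gates
                  if g.name in leaf_names and _is_under(g, parent, by_name)]
        if not leaves:
            raise ValueError(f"sequencing budget for {parent!r} has no leaf gates")
        counts = _allocate(budget, leaves)
        for g in sorted(leaves, key=lambda x: x.name):
            n = counts[g.name]
            if config.mode == "prescribed":
                if g.truth is None:
                    raise ValueError(f"leaf {g.name} lacks a prescribed truth")
                divisions = rng.choice(ks, size=n, p=ps)
                stops = rng.random(n) < g.truth
                for j in range(n):
                    seq, has_stop, has_fs = _prescribed_sequence(
                        template, pweights, rng, int(divisions[j]), p_m,
                        bool(stops[j]), config.frameshift_share)
                    rows.append({
                        "cell_id": f"{g.name}_c{j:04d}", "gate": g.name,
                        "divisions": int(divisions[j]),
                        "has_stop": has_stop, "has_frameshift": has_fs,
                        "seq": seq,
                    })
            else:
                spec = config.divisions_by_gate.get(g.name, config.max_divisions)
                division_spec = (snapshot_division_distribution(spec)
                                 if isinstance(spec, int) else spec)
                sim = SimConfig(mu=config.mu, p_del=config.p_del, mode="bernoulli")
                cohort = simulate_cohort(template, partition, sim, division_spec,
                                         n, rng, cell_id_prefix=f"{g.name}_c")
                for cell in cohort:
                    rows.append({
                        "cell_id": cell.cell_id, "gate": g.name,
                        "divisions": cell.divisions_completed,
                        "has_stop": cell.has_stop,
                        "has_frameshift": cell.has_frameshift,
                        "seq": cell.seq,
                    })
    return pd.DataFrame(rows)


def _is_under(gate: GateSpec, ancestor: str, by_name: Mapping[str, GateSpec]) -> bool:
    name = gate.name
    while name is not None:
        if name == ancestor:
            return True
        name = by_name[name].parent
    return False


def _index_channels(cells: pd.DataFrame, config: ScenarioConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Synthetic index-sort table: gate-conditional Gaussian channel values
    on an arbitrary log-like scale (no cytometer physics intended)."""
    by_name = {g.name: g for g in config.gates}
    bcr_mu = cells["gate"].map(lambda g: by_name[g].channel_bcr
                               if by_name[g].channel_bcr is not None else 2.5)
    cx_mu = cells["gate"].map(lambda g: by_name[g].channel_cxcr4
                              if by_name[g].channel_cxcr4 is not None else 2.5)
    return pd.DataFrame({
        "cell_id": cells["cell_id"],
        "gate": cells["gate"],
        "channel_bcr": rng.normal(bcr_mu.to_numpy(float), 0.25),
        "channel_cxcr4": rng.normal(cx_mu.to_numpy(float), 0.25),
    })


def _read_with_errors(seq: str, error_rate: float, rng: np.random.Generator) -> str:
    if error_rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), error_rate)
    for _ in range(n_err):
        i = int(rng.integers(0, len(arr)))
        arr[i] = BASES[int(rng.integers(0, 4))]
    return "".join(arr)


def _contaminant_sequence(template: VGeneTemplate, rng: np.random.Generator,
                          existing: set) -> str:
    """A unique sequencing-error sequence: the template with a handful of
    random substitutions (stops allowed — errors do not respect biology)."""
    for _ in range(100):
        seq = list(template.seq)
        for _ in range(int(rng.integers(3, 7))):
            i = int(rng.integers(0, len(seq)))
            seq[i] = BASES[int(rng.integers(0, 4))]
        s = "".join(seq)
        if s not in existing:
            return s
    raise RuntimeError("could not build a unique contaminant sequence")


def emit_sequencing(cells: pd.DataFrame, config: ScenarioConfig,
                    template: VGeneTemplate, rng: np.random.Generator,
                    ) -> tuple[dict, dict, dict]:
    """Build per-gate Sanger and NGS samples from the generated cells.

    Returns (sanger_samples, ngs_samples, contaminant_ids).  NGS reads per
    cell are negative-binomial distributed; contaminants are injected at a
    fixed sub-threshold number of reads each.
    """
    seqspec = config.sequencing
    sanger: dict[str, SampleReads] = {}
    ngs: dict[str, SampleReads] = {}
    contaminants: dict[str, list[str]] = {}
    mean = seqspec.reads_per_cell_mean
    k = seqspec.reads_per_cell_dispersion
    p_nb = k / (k + mean)

    for gate, sub in cells.groupby("gate", sort=True):
        n_cells = len(sub)
        if seqspec.emit_sanger:
            sanger[gate] = SampleReads(
                sample_id=gate, n_cells_sorted=n_cells,
                reads=list(zip(sub["cell_id"], sub["seq"])), mode="sanger",
            )
        if seqspec.emit_ngs:
            reads: list[tuple[str, str]] = []
            for cell_id, seq in zip(sub["cell_id"], sub["seq"]):
                r = int(rng.negative_binomial(k, p_nb))
                for j in range(r):
                    reads.append((f"{cell_id}_r{j:03d}",
                                  _read_with_errors(seq, seqspec.error_rate, rng)))
            cell_seqs = set(sub["seq"])
            ids = []
            n_contam_reads = max(1, round(seqspec.contaminant_cells_worth * mean))
            for c in range(seqspec.contaminants_per_sample):
                cseq = _contaminant_sequence(template, rng, cell_seqs)
                cell_seqs.add(cseq)
                cid = f"{gate}_contam{c:02d}"
                ids.append(cid)
                for j in range(n_contam_reads):
                    reads.append((f"{cid}_r{j:03d}", cseq))
            contaminants[gate] = ids
            ngs[gate] = SampleReads(sample_id=gate, n_cells_sorted=n_cells,
                                    reads=reads, mode="ngs")
    return sanger, ngs, contaminants


def _rollup_truth(config: ScenarioConfig) -> dict:
    """Configured true frequency of every gate, percent, by weighting leaf
    truths with pre-enrichment fractions (prescribed mode only)."""
    by_name = {g.name: g for g in config.gates}
    children: dict[str, list[GateSpec]] = {g.name: [] for g in config.gates}
    for g in config.gates:
        if g.parent is not None:
            children[g.parent].append(g)

    def truth(name: str) -> float | None:
        g = by_name[name]
        if not children[name]:
            return None if g.truth is None else 100.0 * g.truth
        parts = [(c.fraction_of_parent, truth(c.name)) for c in children[name]]
        if any(t is None for _, t in parts):
            return None
        return sum(f * t for f, t in parts)

    return {name: truth(name) for name in by_name}


def generate_scenario(config: ScenarioConfig | str, seed: int = 0) -> ScenarioData:
    """Generate one complete synthetic dataset, deterministically per seed."""
    if isinstance(config, str):
        config = preset_config(config)
    else:
        config = copy.deepcopy(config)
    rng = np.random.default_rng(seed)
    template = generate_template(config.template_codons, config.cdr_fraction, rng)
    motifs = find_hotspot_motifs(template, config.motif_patterns)
    partition = partition_regions(template, motifs)
    tree = GatingTree([GateNode(g.name, g.parent, g.fraction_of_parent)
                       for g in config.gates])
    cells = generate_population(config, template, partition, rng)
    index_table = _index_channels(cells, config, rng)
    sanger, ngs, contaminants = emit_sequencing(cells, config, template, rng)

    by_gate = cells.groupby("gate")
    empirical = {
        gate: {
            "n_sequenced": int(len(sub)),
            "n_stop_true": int((sub["has_stop"] | sub["has_frameshift"]).sum()),
        }
        for gate, sub in by_gate
    }
    spec_by_name = {g.name: g for g in config.gates}
    ground_truth = {
        "seed": seed,
        "mode": config.mode,
        "gate_truth_percent": _rollup_truth(config) if config.mode == "prescribed" else {},
        "leaves": {
            gate: {
                "fraction_of_parent": spec_by_name[gate].fraction_of_parent,
                "enrichment": spec_by_name[gate].enrichment,
                "configured_truth": spec_by_name[gate].truth,
                **empirical[gate],
            }
            for gate in empirical
        },
    }
    return ScenarioData(config=config, seed=seed, template=template,
                        partition=partition, tree=tree, cells=cells,
                        index_table=index_table, sanger_samples=sanger,
                        ngs_samples=ngs, contaminant_ids=contaminants,
                        ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# on-disk emission
# ---------------------------------------------------------------------------

def write_scenario(data: ScenarioData, outdir) -> dict:
    """Write a scenario to disk in plain-text formats.

    Emits template.fasta, cdrs.bed, tree.yaml, cells_truth.tsv, index.csv,
    manifest.csv, ground_truth.json, sanger/<gate>.fasta and
    ngs/<gate>.fastq.  Returns a dict of the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    fasta = outdir / "template.fasta"
    with open(fasta, "w") as fh:
        fh.write(f">{data.template.id}\n{data.template.seq}\n")
    paths["template"] = str(fasta)

    bed = outdir / "cdrs.bed"
    with open(bed, "w") as fh:
        for i, (s, e) in enumerate(data.template.cdr_intervals, 1):
            fh.write(f"{data.template.id}\t{s}\t{e}\tCDR{i}\n")
    paths["cdrs"] = str(bed)

    tree_path = outdir / "tree.yaml"
    data.tree.to_yaml(tree_path)
    paths["tree"] = str(tree_path)

    cells_path = outdir / "cells_truth.tsv"
    data.cells.to_csv(cells_path, sep="\t", index=False)
    paths["cells_truth"] = str(cells_path)

    index_path = outdir / "index.csv"
    data.index_table.to_csv(index_path, index=False)
    paths["index"] = str(index_path)

    manifest_rows = []
    if data.sanger_samples:
        (outdir / "sanger").mkdir(exist_ok=True)
        for gate, sample in sorted(data.sanger_samples.items()):
            p = outdir / "sanger" / f"{gate}.fasta"
            with open(p, "w") as fh:
                for rid, seq in sample.reads:
                    fh.write(f">{rid}\n{seq}\n")
            manifest_rows.append({"sample_id": gate,
                                  "file": str(p.relative_to(outdir)),
                                  "n_cells_sorted": sample.n_cells_sorted,
                                  "mode": "sanger"})
    if data.ngs_samples:
        (outdir / "ngs").mkdir(exist_ok=True)
        for gate, sample in sorted(data.ngs_samples.items()):
            p = outdir / "ngs" / f"{gate}.fastq"
            with open(p, "w") as fh:
                for rid, seq in sample.reads:
                    fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")
            manifest_rows.append({"sample_id": gate,
                                  "file": str(p.relative_to(outdir)),
                                  "n_cells_sorted": sample.n_cells_sorted,
                                  "mode": "ngs"})
    manifest_path = outdir / "manifest.csv"
    pd.DataFrame(manifest_rows).to_csv(manifest_path, index=False)
    paths["manifest"] = str(manifest_path)

    gt_path = outdir / "ground_truth.json"
    with open(gt_path, "w") as fh:
        json.dump(data.ground_truth, fh, indent=2, default=float)
    paths["ground_truth"] = str(gt_path)
    return paths
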