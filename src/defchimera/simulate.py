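"""Synthetic defensin gene families, spiked transcript pools and reads.

Everything downstream of annotation can be exercised without downloads by
emulating the study system: a tandem-duplicated family of two-exon genes
encoding ~92-aa pre-pro-proteins (19-aa signal, ~33-aa mature peptide with
six family-conserved cysteines) at high inter-gene identity; a transcript
pool in which the family carries ~85.19% of all mRNA with one dominant
gene (~16.4% of the family, the Defa24 regime) and a ~0.24% chimeric
spike; and 60-80 bp single- or paired-end reads with a uniform
substitution error model and a per-read truth table.

Family generation works backwards from a random valid ancestor: a mature
peptide with the cysteine scaffold (and a cationic bias) is embedded in a
pre-pro-protein, reverse-translated, and per-gene point mutations are
applied to non-protected positions to reach the target pairwise identity;
codons that would create a stop or touch the cysteine scaffold are
reverted, so every gene satisfies the gene-model invariants by
construction.  A single global seed derives per-stage seeds by fixed
offsets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from defchimera.chimera import ChimericTranscript, DefensinGene, STOPS

__all__ = [
    "FamilyConfig",
    "PoolConfig",
    "TranscriptPool",
    "ReadSet",
    "make_family",
    "make_pool",
    "simulate_reads",
    "mean_pairwise_identity",
    "write_family",
    "write_fastq",
]

_AA_ALPHABET = "ARNDCQEGHILKMFPSTWYV"
# codon table restricted to what we need: one codon list per amino acid
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "N": ["AAT", "AAC"], "D": ["GAT", "GAC"], "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"], "E": ["GAA", "GAG"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "K": ["AAA", "AAG"],
    "M": ["ATG"], "F": ["TTT", "TTC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"], "V": ["GTT", "GTC", "GTA", "GTG"],
}
_BASES = "ACGT"
_CYS_CODONS = {"TGT", "TGC"}


@dataclass(frozen=True)
class FamilyConfig:
    """Parameters of a synthetic defensin-like gene family."""

    n_genes: int = 28
    identity: float = 0.90      # target mean pairwise nucleotide identity
    prepro_len: int = 92        # aa, incl. Met
    signal_len: int = 19        # aa
    mature_len: int = 33        # aa, six conserved cysteines
    n_cys: int = 6
    exon1_frac: float = 0.43    # fraction of the CDS carried by exon 1
    seed: int = 0


@dataclass(frozen=True)
class PoolConfig:
    """Abundance structure of the transcript pool and the read library."""

    chimera_fraction: float = 0.0024   # chimeric share of family mRNA
    family_fraction: float = 0.8519    # family share of all mRNA
    dominant_share: float = 0.164      # top gene's share of the family
    lognormal_sigma: float = 2.0       # spread of per-gene abundances
    n_background: int = 3              # non-family transcripts (decoy role)
    background_len: int = 600
    n_reads: int = 1_000_000
    read_len: int = 70                 # typical read length is 60-80 bp
    error_rate: float = 0.001          # per-base substitution rate
    paired: bool = False
    seed: int = 0


def _rng(seed: int, stage: int) -> np.random.Generator:
    # fixed per-stage offsets keep stages independent but reproducible
    return np.random.default_rng(int(seed) * 1000 + stage)


def mean_pairwise_identity(genes: Sequence[DefensinGene]) -> float:
    """Mean fraction of identical positions over all gene pairs (equal-length CDS)."""
    seqs = [np.frombuffer(g.cds.encode(), dtype=np.uint8) for g in genes]
    if len(seqs) < 2:
        return 1.0
    idents = []
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            idents.append((seqs[i] == seqs[j]).mean())
    return float(np.mean(idents))


def make_family(config: FamilyConfig) -> list[DefensinGene]:
    """Generate a deterministic defensin-like gene family.

    Raises ValueError when the identity target is lower than the fraction
    of positions that must stay conserved (start, stop and cysteine
    codons), which would make the target unreachable.
    """
    cfg = config
    rng = _rng(cfg.seed, 1)
    n_aa = cfg.prepro_len
    mature_start = n_aa - cfg.mature_len
    if cfg.signal_len >= mature_start:
        raise ValueError("signal peptide overlaps the mature region")

    # conserved cysteine offsets, spread over the mature peptide
    cys_off = np.sort(rng.choice(
        np.arange(1, cfg.mature_len - 1), size=cfg.n_cys, replace=False))
    while np.any(np.diff(cys_off) < 2):  # keep scaffold positions separated
        cys_off = np.sort(rng.choice(
            np.arange(1, cfg.mature_len - 1), size=cfg.n_cys, replace=False))

    # ancestor protein: Met + random residues (no extra Cys anywhere), with a
    # cationic bias (R/K-rich) in the mature region as in real defensins
    body = [a for a in _AA_ALPHABET if a != "C"]
    cationic = list("RK")
    prot = ["M"]
    for i in range(1, n_aa):
        if i >= mature_start and (i - mature_start) in cys_off:
            prot.append("C")
        elif i >= mature_start and rng.random() < 0.25:
            prot.append(cationic[rng.integers(len(cationic))])
        else:
            prot.append(body[rng.integers(len(body))])
    ancestor_aa = "".join(prot)

    codons = [_CODONS[a][rng.integers(len(_CODONS[a]))] for a in ancestor_aa]
    codons.append(["TAA", "TGA"][rng.integers(2)])
    ancestor = "".join(codons)
    n_nt = len(ancestor)

    protected = np.zeros(n_nt, dtype=bool)
    protected[:3] = True            # start codon
    protected[-3:] = True           # stop codon
    for off in cys_off:
        c = (mature_start + int(off)) * 3
        protected[c:c + 3] = True
    if cfg.identity < protected.mean():
        raise ValueError(
            "identity target below the conserved-position floor; "
            "cysteine conservation would be impossible")

    exon1_len = int(round(n_nt * cfg.exon1_frac))
    if not 0 < exon1_len < mature_start * 3:
        raise ValueError("exon1_frac must leave the mature region in exon 2")

    # per-gene per-site mutation probability: two independent lineages each
    # mutating at rate q give pairwise divergence ~2q; correct for the
    # conserved positions that can never diverge
    q = (1.0 - cfg.identity) / 2.0 / max(1e-9, 1.0 - protected.mean())
    genes: list[DefensinGene] = []
    for g in range(cfg.n_genes):
        grng = _rng(cfg.seed, 100 + g)
        seq = list(ancestor)
        mutate = (grng.random(n_nt) < q) & ~protected
        for pos in np.flatnonzero(mutate):
            old = seq[pos]
            choices = [b for b in _BASES if b != old]
            seq[pos] = choices[grng.integers(3)]
        # repair: revert codons that became stops or touched the Cys count
        for ci in range(0, n_nt - 3, 3):
            cod = "".join(seq[ci:ci + 3])
            anc = ancestor[ci:ci + 3]
            if cod == anc:
                continue
            if cod in STOPS or (cod in _CYS_CODONS and anc not in _CYS_CODONS):
                seq[ci:ci + 3] = list(anc)
        cds = "".join(seq)
        genes.append(DefensinGene(
            gene_id=f"DefS{g + 1:02d}",
            exon1_cds=cds[:exon1_len],
            exon2_cds=cds[exon1_len:],
            signal_len=cfg.signal_len,
            mature_start=mature_start,
            mature_len=cfg.mature_len,
        ))
    return genes


@dataclass
class TranscriptPool:
    """Transcripts with molecule-level abundances and a truth table."""

    ids: list[str]
    seqs: list[str]
    roles: list[str]
    weights: np.ndarray              # molecule fractions, sum to 1
    truth: pd.DataFrame = field(default_factory=pd.DataFrame)

    def transcripts(self) -> list[tuple[str, str, str]]:
        return list(zip(self.ids, self.seqs, self.roles))


def _random_transcript(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def make_pool(
    family: Sequence[DefensinGene],
    chimeras: Sequence[ChimericTranscript],
    config: PoolConfig,
) -> TranscriptPool:
    """Assemble the transcript pool with the study's abundance structure.

    Parental abundances are log-normal with the top gene pinned to
    ``dominant_share`` of the family; chimeras share ``chimera_fraction``
    of the family budget (log-normal weights); background transcripts
    (role ``decoy``) fill the remaining ``1 - family_fraction``.
    """
    cfg = config
    if not 0 <= cfg.chimera_fraction < 1:
        raise ValueError("chimera_fraction must be in [0, 1)")
    if cfg.chimera_fraction > 0 and not chimeras:
        raise ValueError("chimera_fraction > 0 but no chimeras supplied")
    rng = _rng(cfg.seed, 2)

    w_par = rng.lognormal(mean=0.0, sigma=cfg.lognormal_sigma, size=len(family))
    w_par /= w_par.sum()
    if len(family) > 1 and cfg.dominant_share:
        # pin the most abundant gene to the dominant share; flatten the
        # remaining draws just enough that none exceeds it
        d = cfg.dominant_share
        top = int(w_par.argmax())
        logw = np.log(np.delete(w_par, top))
        temp = 1.0
        for _ in range(80):
            others = np.exp(logw / temp)
            others = others / others.sum() * (1.0 - d)
            if others.max() <= d:
                break
            temp *= 1.3
        w_par = np.insert(others, top, d)

    ids = [g.gene_id for g in family]
    seqs = [g.cds for g in family]
    roles = ["parental"] * len(family)
    weights = list(w_par * cfg.family_fraction * (1 - cfg.chimera_fraction))

    if chimeras and cfg.chimera_fraction > 0:
        w_chi = rng.lognormal(mean=0.0, sigma=1.0, size=len(chimeras))
        w_chi /= w_chi.sum()
        for c, w in zip(chimeras, w_chi):
            ids.append(c.chimera_id)
            seqs.append(c.cds)
            roles.append("chimera")
            weights.append(w * cfg.family_fraction * cfg.chimera_fraction)

    bg_total = 1.0 - cfg.family_fraction
    if cfg.n_background > 0 and bg_total > 0:
        w_bg = rng.dirichlet(np.ones(cfg.n_background)) * bg_total
        for i in range(cfg.n_background):
            ids.append(f"background_{i + 1}")
            seqs.append(_random_transcript(rng, cfg.background_len))
            roles.append("decoy")
            weights.append(w_bg[i])

    weights = np.asarray(weights)
    weights /= weights.sum()
    truth = pd.DataFrame({
        "transcript": ids,
        "role": roles,
        "weight": weights,
    })
    return TranscriptPool(ids=ids, seqs=seqs, roles=roles,
                          weights=weights, truth=truth)


@dataclass
class ReadSet:
    """Simulated reads: encoded matrix plus per-read truth."""

    matrix: np.ndarray            # N x L uint8 base codes
    truth: pd.DataFrame           # read_index, source transcript id
    read_len: int
    mate_matrix: np.ndarray | None = None  # reverse-complemented mate 2

    @property
    def n_reads(self) -> int:
        return self.matrix.shape[0]

    def sequences(self) -> list[str]:
        lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
        mat = np.where(self.matrix < 4, self.matrix, 4)
        return [lut[row].tobytes().decode() for row in mat]


def simulate_reads(pool: TranscriptPool, config: PoolConfig) -> ReadSet:
    """Draw reads from the pool: molecule by abundance, start uniform.

    Substitution errors are planted per base at ``error_rate``; paired
    mode emits a second, reverse-complemented mate from the other end of a
    fragment.  Deterministic per seed.
    """
    cfg = config
    rl = cfg.read_len
    shortest = min(len(s) for s in pool.seqs)
    if rl > shortest:
        raise ValueError(f"read_len {rl} exceeds shortest transcript ({shortest})")
    rng = _rng(cfg.seed, 3)

    counts = rng.multinomial(cfg.n_reads, pool.weights)
    mats, mate_mats, src = [], [], []
    from defchimera.quant import encode_seq

    for t, n in enumerate(counts):
        if n == 0:
            continue
        enc = encode_seq(pool.seqs[t])
        starts = rng.integers(0, enc.size - rl + 1, size=n)
        mats.append(enc[starts[:, None] + np.arange(rl)])
        if cfg.paired:
            frag = min(2 * rl + 20, enc.size)
            fstart = np.minimum(starts, enc.size - frag)
            mate = enc[(fstart + frag - rl)[:, None] + np.arange(rl)]
            mate_mats.append((3 - mate)[:, ::-1])  # reverse complement
        src.extend([pool.ids[t]] * n)
    matrix = np.concatenate(mats, axis=0) if mats else np.empty((0, rl), np.uint8)

    def plant_errors(m):
        err = rng.random(m.shape) < cfg.error_rate
        if err.any():
            shift = rng.integers(1, 4, size=int(err.sum())).astype(np.uint8)
            m = m.copy()
            m[err] = (m[err] + shift) % 4
        return m

    matrix = plant_errors(matrix)
    mate_matrix = None
    if cfg.paired:
        mate_matrix = plant_errors(np.concatenate(mate_mats, axis=0))

    truth = pd.DataFrame({"source": src})
    truth["role"] = truth["source"].map(
        dict(zip(pool.ids, pool.roles)))
    return ReadSet(matrix=matrix, truth=truth, read_len=rl,
                   mate_matrix=mate_matrix)


# ---------------------------------------------------------------------------
# On-disk outputs


def write_family(genes: Sequence[DefensinGene], fasta_path: str,
                 meta_path: str) -> None:
    with open(fasta_path, "w") as fh:
        for g in genes:
            fh.write(f">{g.gene_id}\n{g.cds}\n")
    with open(meta_path, "w") as fh:
        fh.write("gene_id\texon1_len\tsignal_len\tmature_start\tmature_len\n")
        for g in genes:
            fh.write(f"{g.gene_id}\t{len(g.exon1_cds)}\t{g.signal_len}"
                     f"\t{g.mature_start}\t{g.mature_len}\n")


def write_fastq(reads: ReadSet, path: str, quality: str = "I") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads.sequences()):
            fh.write(f"@read{i}\n{seq}\n+\n{quality * len(seq)}\n")


def write_config_json(config, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(asdict(config), fh, indent=2)
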