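"""Exhaustive enumeration of theoretical exon-2 chimeric transcripts.

A chimeric alpha-defensin mRNA joins the 5' part of one parental gene (the
*donor*) to the 3' part of another (the *acceptor*) at a breakpoint inside
the exon-2 coding sequence — the exon that encodes the biologically active
mature peptide.  Given a parental gene set, every ordered donor/acceptor
pair is crossed at every exon-2 breakpoint with the acceptor suffix taken
at the same nucleotide offset (the family is near-identical and
homologously alignable, so equal-offset crossover is the default model).

Candidates are filtered: the chimera must be in frame with a single
terminal stop, the mature peptide must keep the six-cysteine scaffold, the
chimera must differ from both parents at both the nucleotide and the
protein level, and per-pair duplicates keep the smallest breakpoint.
Pooled candidates are then purged of anything protein-identical to *any*
parental and collapsed on identical nucleotide sequence.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from Bio.Seq import Seq

__all__ = [
    "DefensinGene",
    "ChimericTranscript",
    "ChimeraSet",
    "generate_pair_chimeras",
    "enumerate_all",
    "check_frame_and_stop",
    "check_cysteine_structure",
    "translate_cds",
]

_VALID_BASES = set("ACGT")
STOPS = {"TAA", "TAG", "TGA"}

CysMode = Literal["count6", "parental_pattern"]


def translate_cds(cds: str) -> str:
    """Translate a CDS, returning the protein without the stop symbol."""
    return str(Seq(cds).translate()).rstrip("*")


@dataclass(frozen=True)
class CheckResult:
    ok: bool
    reason: str | None = None

    def __bool__(self) -> bool:  # allows `if check_frame_and_stop(cds): ...`
        return self.ok


def check_frame_and_stop(cds: str) -> CheckResult:
    """Pass iff length % 3 == 0 with exactly one stop codon, at the end."""
    if not cds:
        raise ValueError("empty CDS")
    if set(cds) - _VALID_BASES:
        raise ValueError(f"non-ACGT characters in CDS: {sorted(set(cds) - _VALID_BASES)}")
    if len(cds) % 3 != 0:
        return CheckResult(False, "frameshift")
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    n_stops = sum(c in STOPS for c in codons)
    if n_stops == 0:
        return CheckResult(False, "no_stop")
    if codons[-1] not in STOPS or n_stops > 1:
        return CheckResult(False, "premature_stop")
    return CheckResult(True)


def check_cysteine_structure(
    mature_peptide: str,
    mode: CysMode = "count6",
    parental_patterns: Sequence[tuple[int, ...]] | None = None,
    n_cys: int = 6,
) -> CheckResult:
    """Check the conserved cysteine scaffold of a mature peptide.

    ``count6`` requires exactly six cysteines in the mature region.
    ``parental_pattern`` additionally requires the cysteine offsets to match
    one of the supplied parental offset vectors.
    """
    offsets = tuple(i for i, aa in enumerate(mature_peptide) if aa == "C")
    if len(offsets) != n_cys:
        return CheckResult(False, "cysteine_count")
    if mode == "parental_pattern":
        if not parental_patterns:
            raise ValueError("parental_pattern mode needs parental_patterns")
        if offsets not in {tuple(p) for p in parental_patterns}:
            return CheckResult(False, "cysteine_pattern")
    elif mode != "count6":
        raise ValueError(f"unknown cysteine mode {mode!r}")
    return CheckResult(True)


@dataclass(frozen=True)
class DefensinGene:
    """A two-exon defensin gene model in CDS orientation.

    The pre-pro-protein (~92 aa) consists of a signal peptide (19 aa), a pro
    region, and the mature antimicrobial peptide (~33 aa, six cysteines)
    encoded by exon 2.  ``mature_start`` is the 0-based amino-acid offset of
    the mature peptide within the pre-pro-protein.
    """

    gene_id: str
    exon1_cds: str
    exon2_cds: str
    signal_len: int = 19
    mature_start: int = 59
    mature_len: int = 33

    def __post_init__(self) -> None:
        chk = check_frame_and_stop(self.cds)
        if not chk:
            raise ValueError(f"{self.gene_id}: invalid CDS ({chk.reason})")
        mat = self.mature_peptide
        if len(mat) != self.mature_len:
            raise ValueError(f"{self.gene_id}: mature region truncated")
        if mat.count("C") != 6:
            raise ValueError(f"{self.gene_id}: mature peptide must have 6 cysteines")

    @property
    def cds(self) -> str:
        return self.exon1_cds + self.exon2_cds

    @property
    def prepro_protein(self) -> str:
        return translate_cds(self.cds)

    @property
    def mature_peptide(self) -> str:
        p = self.prepro_protein
        return p[self.mature_start:self.mature_start + self.mature_len]

    @property
    def cys_offsets(self) -> tuple[int, ...]:
        return tuple(i for i, aa in enumerate(self.mature_peptide) if aa == "C")


@dataclass(frozen=True)
class ChimericTranscript:
    """Donor prefix + acceptor suffix joined inside exon-2 CDS.

    ``breakpoint`` is the nucleotide offset from the exon-2 CDS start: the
    chimera CDS is ``donor.exon1 + donor.exon2[:breakpoint] +
    acceptor.exon2[breakpoint:]``.
    """

    donor_id: str
    acceptor_id: str
    breakpoint: int
    cds: str
    protein: str
    mature_peptide: str
    #: nucleotide offset of the donor/acceptor boundary within the chimera CDS
    junction_nt: int = 0

    @property
    def chimera_id(self) -> str:
        return f"{self.donor_id}-{self.acceptor_id}:{self.breakpoint}"

    @property
    def junction_aa(self) -> int:
        """Amino-acid offset of the junction within the protein (floor)."""
        return self.junction_nt // 3


def _build_chimera(donor: DefensinGene, acceptor: DefensinGene,
                   breakpoint: int) -> tuple[str, int]:
    """Return (cds, junction_nt) where junction_nt is the offset of the
    donor/acceptor boundary within the chimera CDS."""
    cds = donor.exon1_cds + donor.exon2_cds[:breakpoint] + acceptor.exon2_cds[breakpoint:]
    return cds, len(donor.exon1_cds) + breakpoint


def junction_aa_of(donor: DefensinGene, breakpoint: int) -> int:
    """Junction position in protein coordinates (0-based, floor of nt/3)."""
    return (len(donor.exon1_cds) + breakpoint) // 3


@dataclass
class ChimeraSet:
    """Deduplicated candidate chimeras with full filter provenance."""

    members: list[ChimericTranscript] = field(default_factory=list)
    #: (donor_id, acceptor_id, breakpoint, filter_name) for every rejection
    rejected: list[tuple[str, str, int, str]] = field(default_factory=list)
    stats: Counter = field(default_factory=Counter)
    #: nucleotide sequence -> every (donor, acceptor, breakpoint) producing it
    provenance: dict[str, list[tuple[str, str, int]]] = field(default_factory=dict)

    def nucleotide_sequences(self) -> set[str]:
        return {m.cds for m in self.members}

    def __len__(self) -> int:
        return len(self.members)


def _pair_candidates(donor: DefensinGene, acceptor: DefensinGene,
                     cys_mode: CysMode, parental_patterns):
    """Yield (breakpoint, cds, protein, mature, fail_reason|None)."""
    max_b = min(len(donor.exon2_cds), len(acceptor.exon2_cds))
    parent_cds = {donor.cds, acceptor.cds}
    parent_prot = {donor.prepro_protein, acceptor.prepro_protein}
    for b in range(1, max_b):
        cds, _ = _build_chimera(donor, acceptor, b)
        chk = check_frame_and_stop(cds)
        if not chk:
            yield b, cds, None, None, chk.reason
            continue
        protein = translate_cds(cds)
        mature = protein[donor.mature_start:donor.mature_start + donor.mature_len]
        cchk = check_cysteine_structure(mature, cys_mode, parental_patterns)
        if not cchk:
            yield b, cds, protein, mature, cchk.reason
            continue
        if cds in parent_cds:
            yield b, cds, protein, mature, "identical_nt_to_parent"
            continue
        if protein in parent_prot:
            yield b, cds, protein, mature, "identical_protein_to_parent"
            continue
        yield b, cds, protein, mature, None


def generate_pair_chimeras(
    donor: DefensinGene,
    acceptor: DefensinGene,
    cys_mode: CysMode = "count6",
    ledger: ChimeraSet | None = None,
) -> list[ChimericTranscript]:
    """All distinct chimeras of one ordered donor/acceptor pair.

    One candidate per breakpoint in ``[1, len(exon2_cds) - 1]``; filtered for
    frame/stop/cysteine validity and difference from both parents; per-pair
    nucleotide duplicates keep the smallest breakpoint.  Exon-2 lengths
    differing by a non-multiple of 3 simply yield an empty list (every
    candidate is frameshifted).
    """
    patterns = None
    if cys_mode == "parental_pattern":
        patterns = [donor.cys_offsets, acceptor.cys_offsets]
    seen: set[str] = set()
    out: list[ChimericTranscript] = []
    for b, cds, protein, mature, reason in _pair_candidates(
            donor, acceptor, cys_mode, patterns):
        if reason is None and cds in seen:
            reason = "pair_duplicate"
        if reason is not None:
            if ledger is not None:
                ledger.rejected.append((donor.gene_id, acceptor.gene_id, b, reason))
                ledger.stats[reason] += 1
            continue
        seen.add(cds)
        out.append(ChimericTranscript(
            donor_id=donor.gene_id,
            acceptor_id=acceptor.gene_id,
            breakpoint=b,
            cds=cds,
            protein=protein,
            mature_peptide=mature,
            junction_nt=len(donor.exon1_cds) + b,
        ))
    return out


def enumerate_all(
    parentals: Sequence[DefensinGene],
    cys_mode: CysMode = "count6",
    include_self_pairs: bool = True,
) -> ChimeraSet:
    """Enumerate and deduplicate chimeras over every ordered parental pair.

    After pooling the per-pair candidates, any candidate protein-identical
    to *any* parental (not just its own parents) is removed, then identical
    nucleotide sequences are collapsed to one member (the provenance map
    retains every origin).
    """
    if len(parentals) < 2 and not include_self_pairs:
        raise ValueError("need at least 2 parental genes")
    ids = [g.gene_id for g in parentals]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate parental gene ids")

    result = ChimeraSet()
    pooled: list[ChimericTranscript] = []
    for donor in parentals:
        for acceptor in parentals:
            if not include_self_pairs and donor.gene_id == acceptor.gene_id:
                continue
            pooled.extend(
                generate_pair_chimeras(donor, acceptor, cys_mode, ledger=result)
            )
    result.stats["pair_candidates_kept"] = len(pooled)

    parental_proteins = {g.prepro_protein for g in parentals}
    by_seq: dict[str, ChimericTranscript] = {}
    for cand in pooled:
        if cand.protein in parental_proteins:
            result.rejected.append(
                (cand.donor_id, cand.acceptor_id, cand.breakpoint,
                 "identical_protein_to_any_parental"))
            result.stats["identical_protein_to_any_parental"] += 1
            continue
        result.provenance.setdefault(cand.cds, []).append(
            (cand.donor_id, cand.acceptor_id, cand.breakpoint))
        if cand.cds not in by_seq:
            by_seq[cand.cds] = cand
        else:
            result.stats["global_nt_duplicate"] += 1

    result.members = sorted(
        by_seq.values(), key=lambda c: (c.donor_id, c.acceptor_id, c.breakpoint)
    )
    result.stats["members"] = len(result.members)
    return result


# ---------------------------------------------------------------------------
# I/O helpers


def write_chimera_fasta(chimeras: Iterable[ChimericTranscript], nt_path: str,
                        aa_path: str | None = None) -> None:
    with open(nt_path, "w") as fh:
        for c in chimeras:
            fh.write(f">{c.chimera_id}\n{c.cds}\n")
    if aa_path:
        with open(aa_path, "w") as fh:
            for c in chimeras:
                fh.write(f">{c.chimera_id}\n{c.protein}\n")


def read_parental_fasta(fasta_path: str, meta_path: str) -> list[DefensinGene]:
    """Load parentals from a CDS FASTA plus a TSV sidecar.

    Sidecar columns: gene_id, exon1_len, signal_len, mature_start, mature_len.
    """
    from Bio import SeqIO

    meta: dict[str, tuple[int, int, int, int]] = {}
    with open(meta_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            cols = line.rstrip("\n").split("\t")
            meta[cols[idx["gene_id"]]] = (
                int(cols[idx["exon1_len"]]),
                int(cols[idx["signal_len"]]),
                int(cols[idx["mature_start"]]),
                int(cols[idx["mature_len"]]),
            )
    genes = []
    for rec in SeqIO.parse(fasta_path, "fasta"):
        if rec.id not in meta:
            raise ValueError(f"no metadata for {rec.id}")
        e1, sig, ms, ml = meta[rec.id]
        seq = str(rec.seq).upper()
        genes.append(DefensinGene(
            gene_id=rec.id, exon1_cds=seq[:e1], exon2_cds=seq[e1:],
            signal_len=sig, mature_start=ms, mature_len=ml,
        ))
    return genes
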