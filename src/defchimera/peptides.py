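"""In-silico proteolysis and junction-spanning peptide evidence.

Mass-spectrometry evidence for a chimeric protein rests on peptides that
(i) span the donor/acceptor junction with residues on both sides and
(ii) cannot be produced by any parental protein.  This module digests
proteins with simple protease rules (trypsin, Glu-C, elastase), selects
junction-spanning fragments, and checks their uniqueness against a
parental proteome by exhaustive window scanning (a blastp-style
near-substring search at peptide scale).

Enzyme specificities: trypsin cuts after K/R except before P; Glu-C cuts
after E (after D too in phosphate buffers — optional flag); elastase has
broad specificity, modelled as cutting after A, V, S, G, L, I.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Enzyme",
    "ENZYMES",
    "get_enzyme",
    "digest",
    "junction_peptides",
    "uniqueness_check",
    "evidence_report",
    "his6_tag",
    "PeptideMatch",
]


@dataclass(frozen=True)
class Enzyme:
    name: str
    cleave_after: frozenset
    blocked_by_next: frozenset = frozenset()

    def __post_init__(self):
        if not self.cleave_after:
            raise ValueError(f"{self.name}: empty cleavage rule")

    def cut_sites(self, protein: str) -> list[int]:
        """Positions i such that the bond after residue i-1 is cleaved
        (i.e. fragment boundaries, excluding 0 and len)."""
        sites = []
        for i in range(1, len(protein)):
            if protein[i - 1] in self.cleave_after and \
                    protein[i] not in self.blocked_by_next:
                sites.append(i)
        return sites


ENZYMES: dict[str, Enzyme] = {
    "trypsin": Enzyme("trypsin", frozenset("KR"), frozenset("P")),
    "gluc": Enzyme("gluc", frozenset("E")),
    "elastase": Enzyme("elastase", frozenset("AVSGLI")),
}


def get_enzyme(name: str, gluc_cuts_d: bool = False) -> Enzyme:
    if isinstance(name, Enzyme):
        return name
    try:
        enz = ENZYMES[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown enzyme {name!r}; supported: {sorted(ENZYMES)}"
        ) from None
    if enz.name == "gluc" and gluc_cuts_d:
        enz = replace(enz, cleave_after=frozenset("ED"))
    return enz


@dataclass(frozen=True)
class PeptideMatch:
    peptide: str
    source_protein_id: str
    start_aa: int
    spans_junction: bool = False
    unique_vs_parentals: bool = False


def digest(
    protein: str,
    enzyme,
    missed_cleavages: int = 0,
    min_len: int = 4,
    max_len: int = 60,
) -> list[tuple[str, int]]:
    """Digest a protein; returns (peptide, start offset) pairs.

    At 0 missed cleavages and without length filtering the fragments
    concatenate back to the input.  ``min_len``/``max_len`` approximate MS
    observability (the instrument's ~12 kDa peptide-mass ceiling maps to a
    length bound); pass ``min_len=1, max_len=None`` to disable.
    """
    if "*" in protein:
        raise ValueError("protein contains a stop symbol")
    enz = get_enzyme(enzyme)
    bounds = [0] + enz.cut_sites(protein) + [len(protein)]
    out: list[tuple[str, int]] = []
    for i in range(len(bounds) - 1):
        for j in range(i + 1, min(i + 2 + missed_cleavages, len(bounds))):
            pep = protein[bounds[i]:bounds[j]]
            if len(pep) < min_len:
                continue
            if max_len is not None and len(pep) > max_len:
                continue
            out.append((pep, bounds[i]))
    return out


def junction_peptides(
    peptides: Iterable[tuple[str, int]],
    junction_aa: int,
    min_overhang: int = 1,
) -> list[tuple[str, int]]:
    """Peptides with >= min_overhang residues strictly on each side of the
    junction (the boundary between residues junction_aa-1 and junction_aa)."""
    out = []
    for pep, start in peptides:
        end = start + len(pep)
        if start <= junction_aa - min_overhang and end >= junction_aa + min_overhang:
            out.append((pep, start))
    return out


def uniqueness_check(
    peptide: str,
    parental_proteome: Iterable[str],
    max_mismatches: int = 0,
) -> bool:
    """True iff no same-length window of any parental protein matches the
    peptide with at most ``max_mismatches`` substitutions."""
    proteome = list(parental_proteome)
    if not proteome:
        raise ValueError("empty proteome")
    n = len(peptide)
    any_window = False
    for prot in proteome:
        if len(prot) < n:
            continue
        any_window = True
        if max_mismatches == 0:
            if peptide in prot:
                return False
            continue
        for off in range(len(prot) - n + 1):
            mism = 0
            for a, b in zip(peptide, prot[off:off + n]):
                if a != b:
                    mism += 1
                    if mism > max_mismatches:
                        break
            if mism <= max_mismatches:
                return False
    if not any_window:
        warnings.warn("peptide longer than every proteome entry")
    return True


def his6_tag(protein: str) -> str:
    """Append the GSG linker + His6 purification tag used for pull-downs."""
    return protein + "GSG" + "H" * 6


def evidence_report(
    chimera,
    enzymes: Sequence = ("trypsin", "gluc", "elastase"),
    parental_proteome: Iterable[str] = (),
    junction_aa: int | None = None,
    missed_cleavages: int = 0,
    min_len: int = 4,
    max_len: int = 60,
    min_overhang: int = 1,
    max_mismatches: int = 0,
) -> tuple[pd.DataFrame, bool]:
    """All theoretical peptides of a chimeric protein with evidence flags.

    ``chimera`` is a ``ChimericTranscript`` (or any object with ``protein``
    and ``junction_aa``).  Returns a table with one row per (enzyme,
    peptide) flagging ``spans_junction`` and ``unique_vs_parentals``, plus
    the "provable" verdict: at least one peptide with both flags set.
    """
    protein = chimera.protein if hasattr(chimera, "protein") else str(chimera)
    if junction_aa is None:
        junction_aa = chimera.junction_aa
    proteome = list(parental_proteome)
    rows = []
    provable = False
    for enzyme in enzymes:
        enz = get_enzyme(enzyme)
        peps = digest(protein, enz, missed_cleavages=missed_cleavages,
                      min_len=min_len, max_len=max_len)
        spanning = set(junction_peptides(peps, junction_aa, min_overhang))
        for pep, start in peps:
            spans = (pep, start) in spanning
            unique = uniqueness_check(pep, proteome, max_mismatches) \
                if proteome else False
            provable = provable or (spans and unique)
            rows.append((enz.name, pep, start, spans, unique))
    df = pd.DataFrame(
        rows, columns=["enzyme", "peptide", "start_aa",
                       "spans_junction", "unique_vs_parentals"])
    return df, provable
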