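"""Read assignment, TPM quantification and split-read chimera support.

The defensin family is a set of short, near-identical transcripts, so most
reads are compatible with many references.  We mimic decoy-aware selective
quantification with a self-contained pipeline: a k-mer index maps each
k-mer to the set of transcripts containing it; a read's *equivalence class*
is the intersection of the transcript sets of its k-mers (unknown k-mers,
e.g. carrying sequencing errors, are skipped); class counts are resolved to
transcript counts with an expectation-maximisation loop; abundances are
reported as tags per million (TPM) over non-decoy transcripts.  Transcripts
assigned the ``decoy`` role absorb reads during assignment/EM but are
excluded from TPM reporting, reproducing the four decoy index
configurations (parentals only, parentals+chimeras, chimeras as decoys,
parentals as decoys).

Junction-spanning ("split") read support is computed separately: a read is
anchored to two parental transcripts by best ungapped offset and the
breakpoint minimising total mismatches (left part vs one parent, right
part vs the other) is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil, floor
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "ReferenceIndex",
    "QuantResult",
    "SplitReadSupport",
    "build_index",
    "quantify",
    "split_read_support",
    "find_chimeric_reads",
    "occurrence_summary",
    "occurrence_stats",
    "donor_acceptor_totals",
    "tpm_share_percent",
]

_BASE_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lower case

ROLES = {"parental", "chimera", "decoy"}


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string as uint8 codes (255 for non-ACGT)."""
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _kmer_ints_1d(enc: np.ndarray, k: int) -> np.ndarray:
    """2-bit packed k-mer integers for every position of one sequence.

    Positions whose window contains a non-ACGT base get -1.
    """
    n = enc.size
    w = n - k + 1
    if w <= 0:
        return np.empty(0, dtype=np.int64)
    vals = np.zeros(w, dtype=np.int64)
    for j in range(k):
        vals = (vals << 2) | enc[j:j + w].astype(np.int64)
    bad = enc >= 4
    if bad.any():
        cbad = np.concatenate([[0], np.cumsum(bad)])
        vals[(cbad[k:] - cbad[:-k]) > 0] = -1
    return vals


@dataclass
class ReferenceIndex:
    """k-mer index over parental, chimeric and decoy transcripts."""

    ids: list[str]
    seqs: list[str]
    roles: list[str]
    k: int
    #: k-mer integer -> id of a transcript-set in ``sets``
    lookup: dict[int, int]
    #: interned transcript-id sets (frozensets of transcript indices)
    sets: list[frozenset]
    #: k-mer integer -> (transcript, position) of its first occurrence
    pos_lookup: dict[int, tuple[int, int]] = field(default_factory=dict)
    #: cached per-read-length window models
    _window_models: dict = field(default_factory=dict)

    @property
    def n_transcripts(self) -> int:
        return len(self.ids)

    def window_model(self, read_len: int) -> "WindowModel":
        if read_len not in self._window_models:
            self._window_models[read_len] = WindowModel(self, read_len)
        return self._window_models[read_len]

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.seqs])

    def transcripts_with_kmer(self, kmer: str) -> set[str]:
        """Transcript ids containing an exact k-mer (diagnostic helper)."""
        enc = encode_seq(kmer)
        if enc.size != self.k:
            raise ValueError(f"need a {self.k}-mer")
        val = int(_kmer_ints_1d(enc, self.k)[0])
        sid = self.lookup.get(val)
        if sid is None:
            return set()
        return {self.ids[t] for t in self.sets[sid]}


def build_index(
    transcripts: Iterable[tuple[str, str, str]],
    k: int = 21,
) -> ReferenceIndex:
    """Index (id, sequence, role) triples by k-mer.

    Every k-mer of every transcript is covered.  Roles are ``parental``,
    ``chimera`` or ``decoy``; decoys take part in read assignment and EM but
    are dropped from TPM reporting.
    """
    ids, seqs, roles = [], [], []
    for tid, seq, role in transcripts:
        if role not in ROLES:
            raise ValueError(f"{tid}: unknown role {role!r}")
        if len(seq) < k:
            raise ValueError(f"{tid}: sequence shorter than k={k}")
        if tid in ids:
            raise ValueError(f"duplicate transcript id {tid}")
        ids.append(tid)
        seqs.append(seq.upper())
        roles.append(role)

    kmer_tids: dict[int, list[int]] = {}
    pos_lookup: dict[int, tuple[int, int]] = {}
    for t, seq in enumerate(seqs):
        vals = _kmer_ints_1d(encode_seq(seq), k)
        for pos, v in enumerate(vals):
            v = int(v)
            if v >= 0 and v not in pos_lookup:
                pos_lookup[v] = (t, pos)
        for v in np.unique(vals):
            if v < 0:
                continue
            kmer_tids.setdefault(int(v), []).append(t)

    set_ids: dict[frozenset, int] = {}
    sets: list[frozenset] = []
    lookup: dict[int, int] = {}
    for v, tids in kmer_tids.items():
        fs = frozenset(tids)
        sid = set_ids.get(fs)
        if sid is None:
            sid = len(sets)
            set_ids[fs] = sid
            sets.append(fs)
        lookup[v] = sid
    return ReferenceIndex(ids=ids, seqs=seqs, roles=roles, k=k,
                          lookup=lookup, sets=sets, pos_lookup=pos_lookup)


@dataclass
class QuantResult:
    """Per-transcript estimated counts and TPM for one sample."""

    sample_id: str
    counts: dict[str, float]
    tpm: dict[str, float]
    n_reads: int = 0
    n_assigned: int = 0
    roles: dict[str, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (tid, self.roles.get(tid, ""), self.counts.get(tid, 0.0),
             self.tpm.get(tid, 0.0))
            for tid in self.counts
        ]
        return pd.DataFrame(rows, columns=["transcript", "role", "count", "tpm"])


def _reads_as_matrix(reads) -> list[np.ndarray]:
    """Normalise read input to a list of (N x L) uint8 matrices.

    Accepts a list of strings (grouped by length), an (N x L) uint8 matrix,
    or a FASTQ path.
    """
    if isinstance(reads, np.ndarray) and reads.ndim == 2:
        return [reads]
    if isinstance(reads, str):
        import pysam

        seqs = [entry.sequence for entry in pysam.FastxFile(reads)]
        return _reads_as_matrix(seqs)
    if hasattr(reads, "matrix"):  # simulate.ReadSet
        return [reads.matrix]
    groups: dict[int, list[str]] = {}
    for r in reads:
        groups.setdefault(len(r), []).append(r)
    out = []
    for L, rs in sorted(groups.items()):
        buf = np.frombuffer("".join(rs).encode("ascii"), dtype=np.uint8)
        out.append(_BASE_CODE[buf].reshape(len(rs), L))
    return out


class WindowModel:
    """Pre-classified fragment windows of every indexed transcript.

    For a fixed read length L, every transcript of length >= L emits
    windows at ``len - L + 1`` start positions.  Each window is classified
    into the equivalence class of the transcripts containing *all* of its
    k-mers — exactly the rule applied to reads — giving the emission count
    matrix B[t, class].  EM over P(class | t) = B[t, class] / n_windows(t)
    is what makes the near-degenerate defensin family tractable: a chimera
    whose junction windows are never observed in the reads loses mass
    instead of lingering on a flat likelihood ridge.

    Classes containing no parental transcript ("junction classes") also
    receive *cross-emissions* from parentals whose homologous window sits
    within a few substitutions, weighted by the sequencing error model: a
    read that matches a chimera exactly but a highly abundant parental
    with one mismatch is usually a parental read carrying a sequencing
    error, and the EM must be allowed to explain it that way.
    """

    def __init__(self, index: ReferenceIndex, read_len: int,
                 cross_max_mismatches: int = 2):
        self.index = index
        self.read_len = read_len
        self.class_sets: list[frozenset] = []
        self._class_ids: dict[frozenset, int] = {}
        #: class id -> (transcript, window start) of one generating window
        self.class_rep: dict[int, tuple[int, int]] = {}
        #: all-chimera ("junction") class id -> all window starts of the
        #: representative transcript (all members share the window
        #: sequence, so one transcript's windows describe the class)
        self.junction_windows: dict[int, list[int]] = {}
        #: per transcript: class id of the window starting at each position
        self.window_class: list[np.ndarray] = []
        k = index.k
        w_kmers = read_len - k + 1
        rows, cols, vals = [], [], []
        parental_free = {}
        key_memo: dict[bytes, int] = {}  # transient; freed after the build
        for t, seq in enumerate(index.seqs):
            kvals = _kmer_ints_1d(encode_seq(seq), k)
            sids = np.fromiter(
                (index.lookup[int(v)] for v in kvals), dtype=np.int32,
                count=kvals.size)
            n_windows = len(seq) - read_len + 1
            wc = np.empty(n_windows, dtype=np.int32)
            counts: dict[int, int] = {}
            for start in range(n_windows):
                key = np.unique(sids[start:start + w_kmers]).tobytes()
                cls = key_memo.get(key)
                if cls is None:
                    members = self._intersect(
                        np.frombuffer(key, dtype=np.int32))
                    cls = self._intern_class(members)
                    key_memo[key] = cls
                wc[start] = cls
                if cls not in self.class_rep:
                    self.class_rep[cls] = (t, start)
                    parental_free[cls] = all(
                        index.roles[m] == "chimera"
                        for m in self.class_sets[cls])
                if parental_free[cls] and self.class_rep[cls][0] == t:
                    self.junction_windows.setdefault(cls, []).append(start)
                counts[cls] = counts.get(cls, 0) + 1
            self.window_class.append(wc)
            for cls, n in counts.items():
                rows.append(cls)
                cols.append(t)
                vals.append(n)
        self._rows = np.asarray(rows, dtype=np.int64)
        self._cols = np.asarray(cols, dtype=np.int64)
        self._vals = np.asarray(vals, dtype=np.float64)
        self._cross = self._build_cross_emissions(cross_max_mismatches)

    def _build_cross_emissions(self, mmax: int) -> list[tuple[int, int, int, int]]:
        """(class, parental transcript, mismatches, window count) for
        parental-free ("junction") classes.

        Compared at homologous coordinates (same window start), which is
        exact for an equal-length, ungapped-alignable family.  The window
        count scales the emission: every window of the class has a
        homologous parental window that can reproduce it through
        sequencing errors.
        """
        idx = self.index
        parental = [t for t, r in enumerate(idx.roles) if r == "parental"]
        if not parental:
            return []
        encs = {t: encode_seq(idx.seqs[t]) for t in range(idx.n_transcripts)}
        L = self.read_len
        out = []
        for cls, starts in self.junction_windows.items():
            t0 = self.class_rep[cls][0]
            e0 = encs[t0]
            for p in parental:
                pe = encs[p]
                per_m: dict[int, int] = {}
                for start in starts:
                    if pe.size < start + L:
                        continue
                    m = int((pe[start:start + L] != e0[start:start + L]).sum())
                    if 0 < m <= mmax:
                        per_m[m] = per_m.get(m, 0) + 1
                for m, n_win in per_m.items():
                    out.append((cls, p, m, n_win))
        return out

    def _intersect(self, key) -> frozenset:
        sets = self.index.sets
        # smallest sets first: the running intersection collapses quickly
        # and every further step is linear in its (small) size
        members = sorted((sets[int(s)] for s in key if s >= 0), key=len)
        inter = None
        for s in members:
            inter = s if inter is None else inter & s
            if not inter:
                break
        return inter if inter else frozenset()

    def _intern_class(self, members: frozenset) -> int:
        if not members:
            return -1
        cls = self._class_ids.get(members)
        if cls is None:
            cls = len(self.class_sets)
            self._class_ids[members] = cls
            self.class_sets.append(members)
        return cls

    def emission_matrix(self, error_rate: float = 0.001) -> sparse.csr_matrix:
        """P(class | transcript): window counts plus error-model cross
        terms for junction classes."""
        idx = self.index
        eff = np.maximum(idx.lengths - self.read_len + 1, 1).astype(float)
        rows = [self._rows]
        cols = [self._cols]
        vals = [self._vals / eff[self._cols]]
        # relative weight of an m-mismatch explanation vs a perfect match
        rel = error_rate / 3.0 / max(1.0 - error_rate, 1e-9)
        if self._cross:
            c_rows, c_cols, c_vals = [], [], []
            for cls, p, m, n_win in self._cross:
                c_rows.append(cls)
                c_cols.append(p)
                c_vals.append(n_win * rel ** m / eff[p])
            rows.append(np.asarray(c_rows))
            cols.append(np.asarray(c_cols))
            vals.append(np.asarray(c_vals))
        return sparse.csr_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(self.class_sets), idx.n_transcripts))


def _kmer_matrix(enc: np.ndarray, k: int) -> np.ndarray:
    """Packed k-mer integers for a chunk of equal-length reads (-1 where a
    window contains a non-ACGT base)."""
    n, L = enc.shape
    w = L - k + 1
    vals = np.zeros((n, w), dtype=np.int64)
    for j in range(k):
        vals = (vals << 2) | enc[:, j:j + w].astype(np.int64)
    bad = enc >= 4
    if bad.any():
        cbad = np.concatenate(
            [np.zeros((n, 1), dtype=np.int64), np.cumsum(bad, axis=1)], axis=1)
        vals[(cbad[:, k:] - cbad[:, :-k]) > 0] = -1
    return vals


def _em_step(alpha, M, counts, total):
    denom = M @ alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(denom > 0, counts / denom, 0.0)
    alpha_new = alpha * (M.T @ ratio)
    # renormalise: fallback rows make row sums of M slightly exceed 1
    s = alpha_new.sum()
    if s > 0:
        alpha_new *= total / s
    return alpha_new


def _loglik(alpha, M, counts):
    denom = M @ alpha
    pos = counts > 0
    with np.errstate(divide="ignore"):
        ll = counts[pos] * np.log(np.maximum(denom[pos], 1e-300))
    return float(ll.sum())


def _em(M: sparse.csr_matrix, counts: np.ndarray, n_transcripts: int,
        max_iter: int = 1000, tol: float = 1e-10,
        alpha0: np.ndarray | None = None) -> np.ndarray:
    """SQUAREM-accelerated EM for expected read counts.

    The shared-sequence structure of a defensin family makes plain EM
    converge geometrically at a rate close to 1 (the multi-mapping read
    fraction), so each cycle extrapolates two EM steps (Varadhan-Roland
    squared extrapolation), falling back to the plain step whenever the
    extrapolation does not improve the likelihood.  Stops when the
    relative likelihood gain per cycle drops below ``tol``.
    """
    total = counts.sum()
    if total == 0:
        return np.zeros(n_transcripts)
    if alpha0 is None:
        alpha = np.full(n_transcripts, total / n_transcripts, dtype=float)
    else:
        alpha = np.maximum(alpha0.astype(float), 1e-12 * total)
        alpha *= total / alpha.sum()
    ll = _loglik(alpha, M, counts)
    for _ in range(max_iter):
        a1 = _em_step(alpha, M, counts, total)
        a2 = _em_step(a1, M, counts, total)
        r = a1 - alpha
        v = (a2 - a1) - r
        nv = np.linalg.norm(v)
        if nv == 0:
            alpha, ll = a2, _loglik(a2, M, counts)
            break
        beta = -np.linalg.norm(r) / nv
        cand = alpha - 2.0 * beta * r + beta * beta * v
        np.clip(cand, 0.0, None, out=cand)
        s = cand.sum()
        if s > 0:
            cand *= total / s
        cand = _em_step(cand, M, counts, total)  # stabilising EM step
        ll_cand = _loglik(cand, M, counts)
        ll_em = _loglik(a2, M, counts)
        if ll_cand >= ll_em:
            alpha_new, ll_new = cand, ll_cand
        else:
            alpha_new, ll_new = a2, ll_em
        gain = ll_new - ll
        alpha = alpha_new
        ll = ll_new
        if abs(gain) < tol * max(1.0, abs(ll)):
            break
    return alpha


def quantify(
    reads,
    index: ReferenceIndex,
    max_mismatches: int = 1,
    sample_id: str = "sample",
    read_len: int | None = None,
    error_rate: float = 0.001,
    calibrate_background: bool = True,
    chunk_size: int = 100_000,
) -> QuantResult:
    """Quantify a read set against a reference index.

    ``reads`` may be a list of strings, an encoded (N x L) uint8 matrix, a
    ``simulate.ReadSet`` or a FASTQ path.  Each error-free read is located
    in the reference by k-mer anchoring and joins the equivalence class of
    its window (the transcripts containing all of its k-mers).  With
    ``max_mismatches >= 1``, reads that match no window exactly are
    Hamming-scored against every transcript at the anchored offset and
    snapped to the nearest window's class; at ``max_mismatches = 0`` they
    are left unassigned.  Class counts are resolved by EM over the
    per-transcript window emission model and converted to TPM over
    non-decoy transcripts using effective length ``len - read_len + 1``
    floored at 1.
    """
    matrices = _reads_as_matrix(reads)
    n_reads = sum(m.shape[0] for m in matrices)
    if n_reads == 0:
        warnings.warn("empty read input; returning empty QuantResult")
        return QuantResult(sample_id=sample_id, counts={}, tpm={})

    if read_len is None:
        lens = np.concatenate([np.full(m.shape[0], m.shape[1]) for m in matrices])
        read_len = int(np.bincount(lens.astype(int)).argmax())
    model = index.window_model(read_len)

    # padded transcript matrix for offset verification and rescue
    max_len = int(index.lengths.max())
    P = np.full((index.n_transcripts, max_len), 255, dtype=np.uint8)
    for t, seq in enumerate(index.seqs):
        P[t, :len(seq)] = encode_seq(seq)
    lengths = index.lengths
    pos_lookup = index.pos_lookup
    window_class = model.window_class

    class_counts: dict[int, int] = {}
    unassigned = 0
    for mat in matrices:
        L = mat.shape[1]
        for lo in range(0, mat.shape[0], chunk_size):
            chunk = np.ascontiguousarray(mat[lo:lo + chunk_size])
            kvals = _kmer_matrix(chunk, index.k)
            w = kvals.shape[1]
            anchor_js = (0, w - 1, w // 2)
            for ri in range(chunk.shape[0]):
                read = chunk[ri]
                cls = None
                offset = None
                for j in anchor_js:
                    hit = pos_lookup.get(int(kvals[ri, j]))
                    if hit is None:
                        continue
                    t0, pos = hit
                    o = pos - j
                    if o < 0 or o + L > lengths[t0]:
                        continue
                    if offset is None:
                        offset = o
                    if not (P[t0, o:o + L] != read).any():
                        cls = int(window_class[t0][o])
                        break
                if cls is None:
                    # no anchor verified: align at the anchored offset and
                    # snap to the nearest transcript's window class
                    if offset is None or max_mismatches == 0:
                        unassigned += 1
                        continue
                    mism = (P[:, offset:offset + L] != read).sum(axis=1)
                    t0 = int(mism.argmin())
                    if mism[t0] > L // 4 or offset + L > lengths[t0]:
                        unassigned += 1
                        continue
                    cls = int(window_class[t0][offset])
                class_counts[cls] = class_counts.get(cls, 0) + 1

    counts_vec = np.zeros(len(model.class_sets))
    for cls, n in class_counts.items():
        counts_vec[cls] = n
    M = model.emission_matrix(error_rate=error_rate)
    eff_len = np.maximum(index.lengths - read_len + 1, 1).astype(float)

    roles = np.asarray(index.roles)
    # parsimony start: credit each class to its non-chimeric members when
    # any exist; the likelihood is concave, so the start affects speed only
    alpha0 = np.zeros(index.n_transcripts)
    chim_mask = roles == "chimera"
    for cls, n in class_counts.items():
        members = np.fromiter(model.class_sets[cls], dtype=int)
        non_chim = members[~chim_mask[members]]
        target = non_chim if non_chim.size else members
        alpha0[target] += n / target.size
    alpha = _em(M, counts_vec, index.n_transcripts, alpha0=alpha0)

    # Background calibration of the aggregate chimeric mass.  A sequencing
    # error at a site where a chimera differs from a parental by a single
    # base turns a parental read into a perfect junction read, and with
    # one free abundance per enumerated chimera the likelihood overfits
    # that background.  The aggregate is therefore re-estimated from
    # *strong* junction evidence only — classes at least two substitutions
    # away from every parental window, which single errors cannot reach:
    #     A = J_strong / f_strong
    # with f_strong the mean fraction of a chimera's windows that lie in
    # strong junction classes (abundance is independent of window
    # geometry under the pool model, so the unweighted mean is the right
    # scaling).  Per-chimera EM abundances are rescaled to the calibrated
    # total; the difference returns to the parentals.
    if calibrate_background and chim_mask.any():
        weak = {cls for cls, p, m, nw in model._cross if m <= 1}
        strong = {cls for cls in model.junction_windows if cls not in weak}
        j_strong = float(sum(
            n for cls, n in class_counts.items() if cls in strong))
        f_c = np.zeros(index.n_transcripts)
        for cls in strong:
            n_win = len(model.junction_windows[cls])
            for t in model.class_sets[cls]:
                f_c[t] += n_win
        f_c /= eff_len
        a_em = alpha[chim_mask].sum()
        f_bar = float(f_c[chim_mask].mean())
        if f_bar > 0 and a_em > 0:
            a_cal = j_strong / f_bar
            alpha[chim_mask] *= a_cal / a_em
            par_mask = roles == "parental"
            diff = a_em - a_cal
            if alpha[par_mask].sum() > 0:
                alpha[par_mask] *= 1.0 + diff / alpha[par_mask].sum()
                np.clip(alpha, 0.0, None, out=alpha)
    reported = roles != "decoy"
    w = alpha / eff_len
    w_rep = np.where(reported, w, 0.0)
    tot = w_rep.sum()
    tpm = w_rep / tot * 1e6 if tot > 0 else w_rep
    counts = {index.ids[t]: float(alpha[t]) for t in range(index.n_transcripts)}
    tpms = {index.ids[t]: float(tpm[t])
            for t in range(index.n_transcripts) if reported[t]}
    return QuantResult(
        sample_id=sample_id,
        counts=counts,
        tpm=tpms,
        n_reads=n_reads,
        n_assigned=n_reads - unassigned,
        roles=dict(zip(index.ids, index.roles)),
    )


# ---------------------------------------------------------------------------
# Split-read support


@dataclass(frozen=True)
class SplitReadSupport:
    """Best two-parent explanation of a read: donor prefix + acceptor suffix."""

    read_id: str
    parent_left: str
    parent_right: str
    breakpoint_in_read: int
    mismatches_left: int
    mismatches_right: int

    @property
    def total_mismatches(self) -> int:
        return self.mismatches_left + self.mismatches_right


def _best_offset(read_enc: np.ndarray, parent_enc: np.ndarray):
    """Best ungapped placement of the read in a parent.

    Returns (offset, per-position mismatch bool array at that offset,
    total mismatches)."""
    L = read_enc.size
    if parent_enc.size < L:
        raise ValueError("read longer than parent")
    windows = np.lib.stride_tricks.sliding_window_view(parent_enc, L)
    mism = (windows != read_enc).sum(axis=1)
    off = int(mism.argmin())
    return off, windows[off] != read_enc, int(mism[off])


def split_read_support(
    read: str,
    parent_left_seq: str,
    parent_right_seq: str,
    read_id: str = "read",
    parent_left: str = "left",
    parent_right: str = "right",
) -> SplitReadSupport | None:
    """Find the breakpoint minimising total mismatches for a parent pair.

    The read is anchored in each parent by best ungapped offset; for every
    breakpoint b the left b bases are compared to the left parent and the
    remainder to the right parent.  Ties go to the smallest breakpoint.
    Returns None ("unsupported") when either side needs more than
    floor(len/4) mismatches.
    """
    r = encode_seq(read)
    L = r.size
    _, neq_l, _ = _best_offset(r, encode_seq(parent_left_seq))
    _, neq_r, _ = _best_offset(r, encode_seq(parent_right_seq))
    cum_l = np.concatenate([[0], np.cumsum(neq_l)])
    cum_r = np.concatenate([[0], np.cumsum(neq_r)])
    tot_r = cum_r[-1]
    totals = cum_l[: L + 1] + (tot_r - cum_r[: L + 1])
    b = int(totals.argmin())  # argmin returns the first (smallest) minimiser
    ml = int(cum_l[b])
    mr = int(tot_r - cum_r[b])
    if ml > L // 4 or mr > L // 4:
        return None
    return SplitReadSupport(
        read_id=read_id, parent_left=parent_left, parent_right=parent_right,
        breakpoint_in_read=b, mismatches_left=ml, mismatches_right=mr,
    )


def find_chimeric_reads(
    reads: Sequence[str],
    parents: Mapping[str, str],
    max_mismatches: int = 1,
    top_n: int = 4,
    read_ids: Sequence[str] | None = None,
) -> list[SplitReadSupport]:
    """Scan reads for junction-spanning support of two-parent chimeras.

    A read is called chimeric when no single parent explains it within
    ``max_mismatches`` but some ordered parent pair does via a split
    alignment with strictly fewer mismatches than the best single parent.
    Only the ``top_n`` single-parent candidates are paired, which is exact
    on a near-identical family.
    """
    ids = list(parents)
    encs = [encode_seq(parents[p]) for p in ids]
    out: list[SplitReadSupport] = []
    for i, read in enumerate(reads):
        r = encode_seq(read)
        L = r.size
        neqs, singles = [], []
        for enc in encs:
            _, neq, tot = _best_offset(r, enc)
            neqs.append(np.concatenate([[0], np.cumsum(neq)]))
            singles.append(tot)
        singles = np.asarray(singles)
        m_single = int(singles.min())
        if m_single <= max_mismatches:
            continue
        order = np.argsort(singles, kind="stable")[:top_n]
        best = None
        for pi in order:
            for pj in order:
                if pi == pj:
                    continue
                totals = neqs[pi][: L + 1] + (neqs[pj][-1] - neqs[pj][: L + 1])
                b = int(totals.argmin())
                cand = (int(totals[b]), b, ids[pi], ids[pj])
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            continue
        tot, b, pl, pr = best
        if tot <= max_mismatches and tot < m_single and 0 < b < L:
            li = ids.index(pl)
            ri = ids.index(pr)
            ml = int(neqs[li][b])
            mr = int(neqs[ri][-1] - neqs[ri][b])
            out.append(SplitReadSupport(
                read_id=read_ids[i] if read_ids else f"read{i}",
                parent_left=pl, parent_right=pr, breakpoint_in_read=b,
                mismatches_left=ml, mismatches_right=mr,
            ))
    return out


# ---------------------------------------------------------------------------
# Occurrence / abundance summaries


def occurrence_stats(total: int, never_found: int, n_band: int,
                     n_le_lo: int, n_ge_hi: int) -> dict:
    """Percentages of the occurrence distribution from its raw counts.

    ``n_band`` counts chimeras detected in the low band (e.g. 1-50
    samples), ``n_le_lo``/``n_ge_hi`` those detected in at most/at least
    the low/high sample-count thresholds.  Percentages are rounded to two
    decimals.
    """
    if total <= 0:
        raise ValueError("total must be positive")
    detected = total - never_found
    pct = lambda x, denom: round(100.0 * x / denom, 2) if denom else float("nan")
    return {
        "total": total,
        "never_found": never_found,
        "detected": detected,
        "never_found_pct": pct(never_found, total),
        "band_count": n_band,
        "band_pct_of_total": pct(n_band, total),
        "band_pct_of_detected": pct(n_band, detected),
        "le_lo_count": n_le_lo,
        "le_lo_pct": pct(n_le_lo, total),
        "ge_hi_count": n_ge_hi,
        "ge_hi_pct": pct(n_ge_hi, total),
    }


def occurrence_summary(
    matrix,
    n_samples: int | None = None,
    frac_lo: float = 1 / 3,
    frac_hi: float = 2 / 3,
    band: tuple[int, int] = (1, 50),
    lo_threshold: int | None = None,
    hi_threshold: int | None = None,
) -> dict:
    """Distribution statistics of a chimera-by-sample detection matrix.

    ``matrix`` is boolean, rows = chimeras, columns = samples.  By default
    the low/high sample-count thresholds are ``floor(frac_lo * n)`` and
    ``ceil(frac_hi * n)``; both can be overridden (e.g. ``hi_threshold=100``
    for 148 samples).
    """
    m = np.asarray(matrix, dtype=bool)
    if n_samples is None:
        n_samples = m.shape[1]
    if n_samples == 0:
        raise ValueError("n_samples must be positive")
    per_row = m.sum(axis=1)
    lo = lo_threshold if lo_threshold is not None else floor(frac_lo * n_samples)
    hi = hi_threshold if hi_threshold is not None else ceil(frac_hi * n_samples)
    stats = occurrence_stats(
        total=m.shape[0],
        never_found=int((per_row == 0).sum()),
        n_band=int(((per_row >= band[0]) & (per_row <= band[1])).sum()),
        n_le_lo=int((per_row <= lo).sum()),
        n_ge_hi=int((per_row >= hi).sum()),
    )
    stats["lo_threshold"] = lo
    stats["hi_threshold"] = hi
    stats["n_samples"] = n_samples
    return stats


def donor_acceptor_totals(
    quant: QuantResult,
    parent_map: Mapping[str, tuple[str, str]],
) -> pd.DataFrame:
    """Per-parent chimeric TPM totals as donor, as acceptor, and combined.

    ``parent_map`` maps chimera transcript ids to (donor, acceptor).  Every
    chimera-role transcript in the quantification must be mapped.
    """
    donors: dict[str, float] = {}
    acceptors: dict[str, float] = {}
    for tid, tpm in quant.tpm.items():
        if quant.roles.get(tid) != "chimera":
            continue
        if tid not in parent_map:
            raise ValueError(f"chimera {tid} missing from parent map")
        d, a = parent_map[tid]
        donors[d] = donors.get(d, 0.0) + tpm
        acceptors[a] = acceptors.get(a, 0.0) + tpm
    parents = sorted(set(donors) | set(acceptors))
    df = pd.DataFrame({
        "donor_tpm": [donors.get(p, 0.0) for p in parents],
        "acceptor_tpm": [acceptors.get(p, 0.0) for p in parents],
    }, index=pd.Index(parents, name="parent"))
    df["total_tpm"] = df["donor_tpm"] + df["acceptor_tpm"]
    return df


def tpm_share_percent(tpm_sum: float, decimals: int = 2) -> float:
    """Share of the per-million budget as a percentage (851910 -> 85.19)."""
    return round(tpm_sum / 1e6 * 100.0, decimals)
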