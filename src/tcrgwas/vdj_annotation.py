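"""Parsimonious V(D)J recombination-scenario assignment.

Each read is assigned germline V/D/J alleles by exact anchored matching,
then the junction between the V and J anchors is decomposed into trimmed
gene ends, an optional D segment, and non-templated insertions.  Among
all exact decompositions the one requiring the fewest N-insertions is
kept (ties broken deterministically).  P-nucleotides are called at
untrimmed gene ends as palindromic extensions of the terminal sequence,
and productivity follows from reading-frame and stop-codon arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GermlineAllele, GermlineReference, RepertoireTable

__all__ = [
    "AnnotationConfig",
    "RecombinationScenario",
    "GeneAlleleGroup",
    "assign_candidate_genes",
    "parsimonious_scenario",
    "call_p_nucleotides",
    "classify_productivity",
    "annotate_read",
    "annotate_repertoire",
    "build_allele_groups",
    "allele_group_map",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
STOP_CODONS = frozenset(("TAA", "TAG", "TGA"))


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AnnotationConfig:
    min_read_len: int = 40
    #: minimum anchored exact match to call a V or J gene at all
    min_vj_anchor: int = 10
    #: D segments shorter than this are reported as V-J insertion instead
    d_min_len: int = 3
    #: maximum palindromic extension per gene end (None = unlimited)
    p_cap: int | None = None


@dataclass
class RecombinationScenario:
    """One read's inferred recombination event.

    Trims count nucleotides removed from each gene's recombination-proximal
    terminus; insertion strings are the read nucleotides not templated by
    any gene segment (P-classified bases included, per the parsimony
    convention).  ``n_vj``/``insert_vj`` are used when no D is called.
    """

    v_allele: str
    j_allele: str
    d_allele: str | None = None
    v_trim: int = 0
    d5_trim: int = 0
    d3_trim: int = 0
    j_trim: int = 0
    n_vd: int | None = None
    n_dj: int | None = None
    n_vj: int | None = None
    insert_vd: str = ""
    insert_dj: str = ""
    insert_vj: str = ""
    p_v: int = 0
    p_d5: int = 0
    p_d3: int = 0
    p_j: int = 0
    productive: bool | None = None
    v_ambiguous: bool = False
    d_ambiguous: bool = False
    j_ambiguous: bool = False
    # read/germline alignment bookkeeping (0-based, half-open)
    v_match_len: int = 0
    v_match_start: int = 0  # position in V allele where the read begins
    j_match_len: int = 0
    j_match_start: int = 0  # position in J allele of the first retained base

    @property
    def total_insertions(self) -> int:
        if self.d_allele is None:
            return int(self.n_vj or 0)
        return int(self.n_vd or 0) + int(self.n_dj or 0)

    @property
    def total_trims(self) -> int:
        return self.v_trim + self.d5_trim + self.d3_trim + self.j_trim


@dataclass(frozen=True)
class GeneAlleleGroup:
    group_id: str
    gene: str
    gene_type: str
    members: tuple[str, ...]
    representative_seq: str


class UnassignableRead(ValueError):
    """Read lacks a V or J anchor and is excluded downstream."""


# ---------------------------------------------------------------------------
# anchored gene matching


def _longest_prefix_in(read: str, target: str, lo: int = 0) -> int:
    """Length of the longest prefix of ``read`` occurring in ``target``."""
    hi = min(len(read), len(target))
    while lo < hi:
        mid = (lo + hi + 1) // 2
        if target.find(read[:mid]) >= 0:
            lo = mid
        else:
            hi = mid - 1
    return lo


def _v_matches(read: str, alleles: Sequence[GermlineAllele],
               seed: int = 0) -> list[tuple[GermlineAllele, int, int]]:
    """(allele, match_len, start_in_allele) for the read 5' anchor.

    The occurrence closest to the allele 3' end is kept so that the
    implied trim is minimal.  ``seed`` is a quick-reject prefix length:
    alleles not containing ``read[:seed]`` are skipped (only valid when
    the caller discards matches shorter than ``seed``).
    """
    out = []
    probe = read[:seed]
    for a in alleles:
        if seed and probe not in a.seq:
            continue
        k = _longest_prefix_in(read, a.seq, lo=seed)
        if k > 0:
            s = a.seq.rfind(read[:k])
            out.append((a, k, s))
    return out


def _j_matches(read: str, alleles: Sequence[GermlineAllele],
               seed: int = 0) -> list[tuple[GermlineAllele, int, int]]:
    """(allele, match_len, start_in_allele) for the read 3' anchor.

    start_in_allele is the allele position of the first retained base;
    the occurrence closest to the allele 5' end minimises the trim.
    """
    rread = read[::-1]
    probe = rread[:seed]
    out = []
    for a in alleles:
        rseq = a.seq[::-1]
        if seed and probe not in rseq:
            continue
        k = _longest_prefix_in(rread, rseq, lo=seed)
        if k > 0:
            s_r = rseq.rfind(rread[:k])
            end_fwd = len(a.seq) - s_r
            out.append((a, k, end_fwd - k))
    return out


def assign_candidate_genes(
    read: str,
    germline: GermlineReference,
    config: AnnotationConfig | None = None,
) -> tuple[list[str], list[str], list[str]]:
    """Candidate V, J and D alleles for one read.

    V candidates maximise the contiguous exact match anchored at the read
    5' end, J candidates likewise at the 3' end; ties are returned as
    sets.  D candidates are alleles with any exact substring match of at
    least ``d_min_len`` inside the junction window.
    """
    config = config or AnnotationConfig()
    if len(read) < config.min_read_len:
        raise UnassignableRead(f"read shorter than {config.min_read_len} nt")
    seed = min(8, config.min_vj_anchor)
    vm = _v_matches(read, germline.by_type("V"), seed=seed)
    jm = _j_matches(read, germline.by_type("J"), seed=seed)
    kv = max((k for _, k, _ in vm), default=0)
    kj = max((k for _, k, _ in jm), default=0)
    if kv < config.min_vj_anchor or kj < config.min_vj_anchor:
        raise UnassignableRead("no V or J anchor of sufficient length")
    v_cands = sorted(a.name for a, k, _ in vm if k == kv)
    j_cands = sorted(a.name for a, k, _ in jm if k == kj)
    window = read[max(0, kv - 0):len(read) - kj] if kv + kj <= len(read) else ""
    d_cands = []
    for a in germline.by_type("D"):
        if _longest_common_substring_len(window, a.seq) >= config.d_min_len:
            d_cands.append(a.name)
    return v_cands, j_cands, sorted(d_cands)


def _longest_common_substring_len(s: str, t: str) -> int:
    if not s or not t:
        return 0
    best = 0
    for L in range(min(len(s), len(t)), 0, -1):
        if L <= best:
            break
        for i in range(len(s) - L + 1):
            if s[i:i + L] in t:
                best = L
                break
    return best


# ---------------------------------------------------------------------------
# parsimony


def _best_d_placement(middle: str, d_alleles: Sequence[GermlineAllele],
                      d_min_len: int):
    """Longest-D decomposition of the junction middle.

    Returns (d_allele, d_len, n_vd, d5_trim) or None when no D segment of
    at least ``d_min_len`` fits.  Ties: shortest allele (fewest D trims),
    then allele name, then leftmost placement in the middle, then
    leftmost placement in the D.
    """
    best = None
    for a in sorted(d_alleles, key=lambda x: (len(x.seq), x.name)):
        for dlen in range(min(len(middle), len(a.seq)), d_min_len - 1, -1):
            if best is not None and dlen < best[1]:
                break
            found = False
            for i in range(len(middle) - dlen + 1):
                pos_d = a.seq.find(middle[i:i + dlen])
                if pos_d >= 0:
                    cand = (a, dlen, i, pos_d)
                    if best is None or dlen > best[1]:
                        best = cand
                    found = True
                    break
            if found:
                break
    return best


def _scenario_rank_key(s: RecombinationScenario,
                       germline: GermlineReference) -> tuple:
    """Deterministic preference order among candidate decompositions.

    Fewest insertions, then fewest total trimmed nucleotides, then the
    longest D segment used, then lexicographic D allele name.
    """
    d_used = 0
    if s.d_allele is not None:
        d_used = len(germline[s.d_allele].seq) - s.d5_trim - s.d3_trim
    return (s.total_insertions, s.total_trims, -d_used, s.d_allele or "")


def parsimonious_scenario(
    read: str,
    v_allele: str,
    j_allele: str,
    d_candidates: Iterable[str],
    germline: GermlineReference,
    config: AnnotationConfig | None = None,
) -> RecombinationScenario:
    """Minimum-N-insertion decomposition of a read given its V and J calls.

    The V (J) anchor is extended maximally into the read: shortening an
    anchored match converts templated bases into junction bases and can
    never reduce the insertion count, so the exhaustive minimum over all
    trim placements is attained at maximal extension (verified against a
    brute-force enumeration oracle in the test suite).
    """
    config = config or AnnotationConfig()
    v = germline[v_allele]
    j = germline[j_allele]
    L = len(read)

    kv = _longest_prefix_in(read, v.seq)
    s_v = v.seq.rfind(read[:kv]) if kv else 0
    rread, rjseq = read[::-1], j.seq[::-1]
    kj = _longest_prefix_in(rread, rjseq)
    if kv == 0 or kj == 0:
        raise UnassignableRead("V/J anchors missing")
    s_r = rjseq.rfind(rread[:kj])
    j_end_fwd = len(j.seq) - s_r

    if kv + kj > L:  # anchors overlap: zero-insertion scenario, no D
        kv_use = L - kj if L - kj >= 0 else 0
        kv_use = max(kv_use, 0)
        # prefer maximal V extension among the overlap splits
        kv_use = min(kv, L)
        kj_use = L - kv_use
        shift = kj - kj_use
        v_trim = len(v.seq) - (s_v + kv_use)
        j_start = j_end_fwd - kj
        j_trim = j_start + shift
        return RecombinationScenario(
            v_allele=v.name, j_allele=j.name, d_allele=None,
            v_trim=v_trim, j_trim=j_trim, n_vj=0, insert_vj="",
            v_match_len=kv_use, v_match_start=s_v,
            j_match_len=kj_use, j_match_start=j_start + shift,
        )

    d_alleles = [germline[name] for name in d_candidates]

    def scenario_at(kv_use: int, kj_use: int) -> RecombinationScenario:
        v_trim = len(v.seq) - (s_v + kv_use)
        j_start = j_end_fwd - kj + (kj - kj_use)
        middle = read[kv_use:L - kj_use]
        placement = _best_d_placement(middle, d_alleles, config.d_min_len)
        if placement is None:
            return RecombinationScenario(
                v_allele=v.name, j_allele=j.name, d_allele=None,
                v_trim=v_trim, j_trim=j_start,
                n_vj=len(middle), insert_vj=middle,
                v_match_len=kv_use, v_match_start=s_v,
                j_match_len=kj_use, j_match_start=j_start,
            )
        d, dlen, n_vd, d5 = placement
        return RecombinationScenario(
            v_allele=v.name, j_allele=j.name, d_allele=d.name,
            v_trim=v_trim, j_trim=j_start,
            d5_trim=d5, d3_trim=len(d.seq) - (d5 + dlen),
            n_vd=n_vd, n_dj=len(middle) - n_vd - dlen,
            insert_vd=middle[:n_vd], insert_dj=middle[n_vd + dlen:],
            v_match_len=kv_use, v_match_start=s_v,
            j_match_len=kj_use, j_match_start=j_start,
        )

    best = scenario_at(kv, kj)
    # Maximal anchor extension is optimal whenever a D segment is already
    # called: shrinking an anchor adds s middle bases but can lengthen the
    # best D match by at most s.  When no D of the minimum length fits,
    # the length threshold breaks that monotonicity — a short anchor
    # retraction can expose a callable D that absorbs the whole middle —
    # so the (rare) D-less case searches over retracted anchors too.
    if best.d_allele is None and d_alleles and best.total_insertions > 0:
        max_d = max(len(d.seq) for d in d_alleles)
        key = _scenario_rank_key(best, germline)
        for s_vv in range(0, min(max_d, kv - 1) + 1):
            for s_jj in range(0, min(max_d, kj - 1) + 1):
                if s_vv == 0 and s_jj == 0:
                    continue
                cand = scenario_at(kv - s_vv, kj - s_jj)
                ck = _scenario_rank_key(cand, germline)
                if ck < key:
                    best, key = cand, ck
    return best


# ---------------------------------------------------------------------------
# P-nucleotides


def _palindromic_extension(gene_end: str, insert: str, side: str,
                           cap: int | None) -> int:
    """Longest palindromic (inverted-repeat) run of ``insert`` off a gene end.

    side='after': insert follows the gene 3' end; P bases are the prefix of
    the insert matching the reverse complement of the gene terminal suffix.
    side='before': insert precedes the gene 5' end; P bases are the suffix
    of the insert matching the reverse complement of the gene initial prefix.
    """
    maxk = min(len(gene_end), len(insert))
    if cap is not None:
        maxk = min(maxk, cap)
    for k in range(maxk, 0, -1):
        if side == "after":
            if insert[:k] == revcomp(gene_end[-k:]):
                return k
        else:
            if insert[-k:] == revcomp(gene_end[:k]):
                return k
    return 0


def call_p_nucleotides(
    scenario: RecombinationScenario,
    germline: GermlineReference,
    cap: int | None = None,
) -> RecombinationScenario:
    """Fill p_v/p_d5/p_d3/p_j; any trimmed end gets p = 0.

    Insertion counts are left at their parsimony values: P-classified
    bases are only removed in the dedicated P-feature analyses.
    """
    v = germline[scenario.v_allele]
    j = germline[scenario.j_allele]
    if scenario.d_allele is None:
        ins = scenario.insert_vj or ""
        p_v = _palindromic_extension(v.seq, ins, "after", cap) if scenario.v_trim == 0 else 0
        p_j = _palindromic_extension(j.seq, ins[p_v:], "before", cap) if scenario.j_trim == 0 else 0
        return replace(scenario, p_v=p_v, p_j=p_j, p_d5=0, p_d3=0)
    d = germline[scenario.d_allele]
    ivd, idj = scenario.insert_vd or "", scenario.insert_dj or ""
    p_v = _palindromic_extension(v.seq, ivd, "after", cap) if scenario.v_trim == 0 else 0
    p_d5 = _palindromic_extension(d.seq, ivd[p_v:], "before", cap) if scenario.d5_trim == 0 else 0
    p_d3 = _palindromic_extension(d.seq, idj, "after", cap) if scenario.d3_trim == 0 else 0
    p_j = _palindromic_extension(j.seq, idj[p_d3:], "before", cap) if scenario.j_trim == 0 else 0
    return replace(scenario, p_v=p_v, p_d5=p_d5, p_d3=p_d3, p_j=p_j)


# ---------------------------------------------------------------------------
# productivity


def classify_productivity(
    read: str,
    scenario: RecombinationScenario,
    germline: GermlineReference,
) -> str:
    """'productive' iff the junction keeps V and J in frame with no stop.

    Frame anchors give the codon phase of each allele's first stored base;
    the read is productive when the phase the J segment lands on in the
    read equals its germline phase and no stop codon occurs in the read's
    coding frame.
    """
    v = germline[scenario.v_allele]
    j = germline[scenario.j_allele]
    # phase of read position i is (v.frame_anchor + v_match_start + i) mod 3
    base = v.frame_anchor + scenario.v_match_start
    q = len(read) - scenario.j_match_len  # J segment start in the read
    in_frame = (base + q) % 3 == (j.frame_anchor + scenario.j_match_start) % 3
    if not in_frame:
        return "non_productive"
    i0 = (-base) % 3  # first full codon start in the read
    for i in range(i0, len(read) - 2, 3):
        if read[i:i + 3] in STOP_CODONS:
            return "non_productive"
    return "productive"


# ---------------------------------------------------------------------------
# allele grouping


def _observed_region(allele: GermlineAllele, span: int | None) -> str:
    if span is None:
        return allele.seq
    if allele.gene_type == "V":
        return allele.seq[-span:]
    if allele.gene_type == "J":
        return allele.seq[:span]
    return allele.seq  # D alleles are short; always fully observed


def build_allele_groups(
    germline: GermlineReference,
    observed_span: int | None = None,
) -> list[GeneAlleleGroup]:
    """Partition alleles: same gene + identical observed-region sequence.

    ``observed_span`` bounds the read-covered region (3' for V, 5' for J);
    None means the full stored sequence is observed.
    """
    buckets: dict[tuple[str, str, str], list[str]] = {}
    for a in germline:
        key = (a.gene_type, a.gene, _observed_region(a, observed_span))
        buckets.setdefault(key, []).append(a.name)
    groups = []
    for (gtype, gene, seq), members in sorted(buckets.items()):
        members = tuple(sorted(members))
        groups.append(GeneAlleleGroup(
            group_id=members[0], gene=gene, gene_type=gtype,
            members=members, representative_seq=seq,
        ))
    return groups


def allele_group_map(groups: Sequence[GeneAlleleGroup]) -> dict[str, str]:
    out = {}
    for g in groups:
        for m in g.members:
            out[m] = g.group_id
    return out


# ---------------------------------------------------------------------------
# per-read and per-repertoire drivers


def annotate_read(
    read: str,
    germline: GermlineReference,
    config: AnnotationConfig | None = None,
    group_of: dict[str, str] | None = None,
) -> RecombinationScenario | None:
    """Full annotation of one read; None when the read is unassignable."""
    config = config or AnnotationConfig()
    try:
        v_cands, j_cands, d_cands = assign_candidate_genes(read, germline, config)
    except UnassignableRead:
        return None
    if group_of is None:
        group_of = allele_group_map(build_allele_groups(germline))
    v_amb = len({group_of[n] for n in v_cands}) > 1
    j_amb = len({group_of[n] for n in j_cands}) > 1
    if not d_cands:
        d_cands = [a.name for a in germline.by_type("D")]
    scen = parsimonious_scenario(read, v_cands[0], j_cands[0], d_cands,
                                 germline, config)
    scen = call_p_nucleotides(scen, germline, cap=config.p_cap)
    productive = classify_productivity(read, scen, germline) == "productive"
    d_amb = False
    if scen.d_allele is not None:
        # alternate D alleles achieving the same used length are ambiguous
        middle = read[scen.v_match_len:len(read) - scen.j_match_len]
        used = len(germline[scen.d_allele].seq) - scen.d5_trim - scen.d3_trim
        others = [
            a for a in germline.by_type("D")
            if a.name != scen.d_allele
            and group_of.get(a.name) != group_of.get(scen.d_allele)
            and _longest_common_substring_len(middle, a.seq) >= used
        ]
        d_amb = bool(others)
    return replace(scen, productive=productive, v_ambiguous=v_amb,
                   j_ambiguous=j_amb, d_ambiguous=d_amb)


_SCEN_COLUMNS = [
    "v_call", "d_call", "j_call", "v_group", "d_group", "j_group",
    "v_trim", "d5_trim", "d3_trim", "j_trim",
    "n_vd", "n_dj", "n_vj", "p_v", "p_d5", "p_d3", "p_j",
    "productive", "v_ambiguous", "d_ambiguous", "j_ambiguous",
]


def _scenario_row(scen: RecombinationScenario, group_of: dict[str, str]) -> tuple:
    has_d = scen.d_allele is not None
    return (
        scen.v_allele,
        scen.d_allele if has_d else None,
        scen.j_allele,
        None if scen.v_ambiguous else group_of.get(scen.v_allele),
        (None if (not has_d or scen.d_ambiguous) else group_of.get(scen.d_allele)),
        None if scen.j_ambiguous else group_of.get(scen.j_allele),
        scen.v_trim,
        scen.d5_trim if has_d else np.nan,
        scen.d3_trim if has_d else np.nan,
        scen.j_trim,
        scen.n_vd if has_d else np.nan,
        scen.n_dj if has_d else np.nan,
        scen.n_vj if not has_d else np.nan,
        scen.p_v, scen.p_d5, scen.p_d3, scen.p_j,
        scen.productive, scen.v_ambiguous, scen.d_ambiguous, scen.j_ambiguous,
    )


def annotate_repertoire(
    table: RepertoireTable,
    germline: GermlineReference,
    config: AnnotationConfig | None = None,
) -> RepertoireTable:
    """Annotate every rearrangement; unassignable reads are dropped.

    Results are cached per unique nucleotide sequence.
    """
    config = config or AnnotationConfig()
    group_of = allele_group_map(build_allele_groups(germline))
    cache: dict[str, tuple | None] = {}
    rows, keep_idx = [], []
    for idx, seq in zip(table.df.index, table.df["sequence"]):
        if seq not in cache:
            scen = annotate_read(seq, germline, config, group_of)
            cache[seq] = None if scen is None else _scenario_row(scen, group_of)
        row = cache[seq]
        if row is not None:
            rows.append(row)
            keep_idx.append(idx)
    out = table.df.loc[keep_idx, ["sequence"]].reset_index(drop=True)
    ann = pd.DataFrame(rows, columns=_SCEN_COLUMNS)
    out = pd.concat([out, ann], axis=1)
    return RepertoireTable(subject_id=table.subject_id, df=out,
                           chain=table.chain)
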