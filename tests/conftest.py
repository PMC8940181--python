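import numpy as np
import pandas as pd
import pytest

from tcrgwas.io_formats import GermlineAllele, GermlineReference
from tcrgwas.synthetic import make_germline, preset_config, simulate_cohort
from tcrgwas.vdj_annotation import annotate_repertoire


@pytest.fixture(scope="session")
def germline():
    return make_germline()


@pytest.fixture(scope="session")
def mini_germline():
    """Hand-crafted tiny germline with controlled junction arithmetic."""
    return GermlineReference([
        # V ends ...CA (for the p_v = 2 worked example)
        GermlineAllele("V1*01", "V1", "V", "ATGGCTGGTCATCTGGAACGTATTACTTCA", 0),
        GermlineAllele("V2*01", "V2", "V", "ATGTCCCGTAAAGAACTGCCGGATTGGGTT", 0),
        # D1 starts with GGG (junction worked example); D2 distinct
        GermlineAllele("D1*01", "D1", "D", "GGGACTAGCTTT", 0),
        GermlineAllele("D2*01", "D2", "D", "TTACCAAGCGCTCCTA", 0),
        # J starts with TC (revcomp GA) for p_j checks
        GermlineAllele("J1*01", "J1", "J", "TCAAAGATCGCTCGTCCGGAAGTT", 0),
        GermlineAllele("J2*01", "J2", "J", "GTCTCTAACCGTATGATCAAACCA", 0),
    ])


@pytest.fixture(scope="session")
def small_cohort():
    return simulate_cohort(preset_config("desk_small"), seed=1)


@pytest.fixture(scope="session")
def annotated_tables(small_cohort, germline):
    """First 25 subjects re-annotated from raw sequences."""
    return [annotate_repertoire(t, germline)
            for t in small_cohort.repertoires[:25]]


# ---------------------------------------------------------------------------
# independent oracles (deliberately brute-force; see module tests)


def brute_force_min_insertions(read: str, v_seq: str, j_seq: str,
                               d_seqs: list[str], d_min_len: int = 3) -> int:
    """Exhaustive enumeration over all exact junction decompositions.

    read = (substring of V, anchored at the read 5' end) + insert
           [+ (substring of D, length >= d_min_len) + insert]
           + (substring of J, anchored at the read 3' end);
    returns the minimum total insertion length.  At least one V and one J
    base must be used (a V and a J gene are called).
    """
    L = len(read)
    best = None
    a_max = 0
    for a in range(1, L + 1):
        if read[:a] in v_seq:
            a_max = a
        else:
            break
    c_max = 0
    for c in range(1, L + 1):
        if read[L - c:] in j_seq:
            c_max = c
        else:
            break
    for a in range(1, a_max + 1):
        for c in range(1, c_max + 1):
            if a + c > L:
                continue
            middle = read[a:L - c]
            candidate = len(middle)  # no D
            for d_seq in d_seqs:
                for dlen in range(min(len(middle), len(d_seq)), d_min_len - 1, -1):
                    hit = False
                    for i in range(len(middle) - dlen + 1):
                        if middle[i:i + dlen] in d_seq:
                            candidate = min(candidate, len(middle) - dlen)
                            hit = True
                            break
                    if hit:
                        break
            if best is None or candidate < best:
                best = candidate
    return best


def brute_force_palindrome(gene_end: str, insert: str, side: str) -> int:
    """Longest palindromic extension by direct base-by-base comparison."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = 0
    if side == "after":
        # insert[0] pairs with gene_end[-1], insert[1] with gene_end[-2], ...
        for i in range(min(len(insert), len(gene_end))):
            if insert[i] == comp[gene_end[-1 - i]]:
                n += 1
            else:
                break
    else:
        for i in range(min(len(insert), len(gene_end))):
            if insert[-1 - i] == comp[gene_end[i]]:
                n += 1
            else:
                break
    return n


def random_read(rng: np.random.Generator, germline, max_trim: int = 8,
                max_ins: int = 8) -> str:
    """A read assembled directly from germline pieces plus random inserts."""
    nts = "ACGT"
    vs = germline.by_type("V")
    ds = germline.by_type("D")
    js = germline.by_type("J")
    v = vs[rng.integers(len(vs))]
    d = ds[rng.integers(len(ds))]
    j = js[rng.integers(len(js))]
    vt = int(rng.integers(0, max_trim + 1))
    jt = int(rng.integers(0, max_trim + 1))
    d5 = int(rng.integers(0, len(d.seq) // 2))
    d3 = int(rng.integers(0, len(d.seq) // 2))
    i1 = "".join(rng.choice(list(nts), size=rng.integers(0, max_ins + 1)))
    i2 = "".join(rng.choice(list(nts), size=rng.integers(0, max_ins + 1)))
    return (v.seq[:len(v.seq) - vt] + i1 + d.seq[d5:len(d.seq) - d3]
            + i2 + j.seq[jt:])
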