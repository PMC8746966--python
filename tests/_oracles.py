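"""Independent brute-force oracles used by unit and acceptance tests.

Everything here recomputes results with direct string slicing and plain
Python arithmetic, deliberately avoiding the package's vectorised code
paths.
"""

from __future__ import annotations

from itertools import accumulate

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(seq))


# ------------------------------------------------------------------ panel

def protospacer_sites_bruteforce(
    reference: str, spacer: str, pam: str = "NGG"
) -> list[tuple[int, str]]:
    """All (cut_position, strand) pairs by scanning every offset directly."""

    def pam_ok(seq: str) -> bool:
        table = {"N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T"}
        return len(seq) == len(pam) and all(
            s in table[p] for s, p in zip(seq, pam)
        )

    k, p = len(spacer), len(pam)
    sites = []
    for i in range(len(reference) - k + 1):
        if reference[i:i + k] == spacer and pam_ok(reference[i + k:i + k + p]):
            sites.append((i + k - 3, "+"))
    rspacer, rpam = rc(spacer), rc(pam)
    for i in range(len(reference) - k + 1):
        if reference[i:i + k] == rspacer and i - p >= 0 and (
            len(reference[i - p:i]) == p
            and all(
                s in {"N": "ACGT", "A": "A", "C": "C", "G": "G", "T": "T"}[q]
                for s, q in zip(reference[i - p:i], rpam)
            )
        ):
            sites.append((i + 3, "-"))
    return sorted(sites)


# ----------------------------------------------------------------- pileup

def pileup_depth_bruteforce(sam_path: str, reference_id: str, start: int, end: int) -> float:
    """Mean depth via per-position counting from pysam reference positions."""
    import pysam

    counts = dict.fromkeys(range(start, end), 0)
    with pysam.AlignmentFile(sam_path, check_sq=False) as af:
        for aln in af.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name != reference_id:
                continue
            for pos in aln.get_reference_positions():
                if start <= pos < end:
                    counts[pos] += 1
    return sum(counts.values()) / (end - start)


# ---------------------------------------------------------------- islands

def cpg_islands_bruteforce(
    seq: str, min_length: int = 200, gc_min: float = 0.5, oe_min: float = 0.6
) -> list[tuple[int, int]]:
    """Window-seeded maximal qualifying intervals, by direct recounting.

    Same declared semantics as the package detector — qualifying
    min_length windows, merged runs, maximal qualifying subintervals,
    left-to-right longest-first overlap resolution — but computed with
    plain prefix lists and per-window slicing.
    """
    n = len(seq)
    if n < min_length:
        return []

    c_pref = [0] + list(accumulate(1 if ch == "C" else 0 for ch in seq))
    g_pref = [0] + list(accumulate(1 if ch == "G" else 0 for ch in seq))
    n_pref = [0] + list(accumulate(1 if ch == "N" else 0 for ch in seq))
    cpg_pref = [0] + list(
        accumulate(1 if seq[i:i + 2] == "CG" else 0 for i in range(n))
    )

    def qualifies(a: int, b: int) -> bool:
        if b - a < min_length:
            return False
        n_c = c_pref[b] - c_pref[a]
        n_g = g_pref[b] - g_pref[a]
        denom = (b - a) - (n_pref[b] - n_pref[a])
        if denom <= 0 or n_c == 0 or n_g == 0:
            return False
        gc = (n_c + n_g) / denom
        n_cpg = cpg_pref[b - 1] - cpg_pref[a] if b - 1 > a else 0
        oe = n_cpg * (b - a) / (n_c * n_g)
        return gc > gc_min and oe > oe_min

    # seed windows, checked by direct slicing to stay independent of the
    # prefix arithmetic above
    def window_qualifies_by_slicing(a: int) -> bool:
        w = seq[a:a + min_length]
        n_c, n_g, n_n = w.count("C"), w.count("G"), w.count("N")
        denom = min_length - n_n
        if denom <= 0 or n_c == 0 or n_g == 0:
            return False
        n_cpg = w.count("CG")
        return (n_c + n_g) / denom > gc_min and (
            n_cpg * min_length / (n_c * n_g) > oe_min
        )

    runs: list[list[int]] = []
    for a in range(n - min_length + 1):
        if window_qualifies_by_slicing(a):
            if runs and a <= runs[-1][1]:
                runs[-1][1] = max(runs[-1][1], a + min_length)
            else:
                runs.append([a, a + min_length])

    islands: list[tuple[int, int]] = []
    for run_a, run_b in runs:
        accepted: list[tuple[int, int]] = []
        for length in range(run_b - run_a, min_length - 1, -1):
            for a in range(run_a, run_b - length + 1):
                b = a + length
                if not qualifies(a, b):
                    continue
                if any(aa <= a and b <= bb and (aa, bb) != (a, b) for aa, bb in accepted):
                    continue
                accepted.append((a, b))
        chosen: list[tuple[int, int]] = []
        for a, b in sorted(accepted, key=lambda iv: (iv[0], -(iv[1] - iv[0]))):
            if all(b <= ca or cb <= a for ca, cb in chosen):
                chosen.append((a, b))
        islands.extend(sorted(chosen))
    return sorted(islands)


# ---------------------------------------------------------------- dotplot

def kmer_self_matches_bruteforce(seq: str, k: int) -> set[tuple[int, int, str]]:
    """All off-diagonal exact k-mer self-matches by pairwise slice comparison."""
    out: set[tuple[int, int, str]] = set()
    n = len(seq)
    for i in range(n - k + 1):
        if "N" in seq[i:i + k]:
            continue
        for j in range(i + 1, n - k + 1):
            if "N" in seq[j:j + k]:
                continue
            if seq[i:i + k] == seq[j:j + k]:
                out.add((i, j, "+"))
            if seq[i:i + k] == rc(seq[j:j + k]):
                out.add((i, j, "-"))
    return out
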