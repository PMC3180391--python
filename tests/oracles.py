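"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and written against the scoring
*definitions*, not against the package's DP/kernel implementations: gap
runs are found by walking strings, optima by exhaustive enumeration of
alignments, and pair scores by explicit double loops.
"""

from __future__ import annotations

from itertools import combinations

GAP = "-"


def affine_run_cost(n: int, g: float, x: float) -> float:
    return g + n * x


def score_pairwise_rows(row_a: str, row_b: str, score, g: float, x: float) -> float:
    """Score an aligned pair of rows: substitution scores on residue-residue
    columns plus g + n*x per maximal residue-vs-gap run, after deleting
    gap-gap columns."""
    total = 0.0
    run = None
    runlen = 0
    for a, b in zip(row_a, row_b):
        if a == GAP and b == GAP:
            continue
        if a == GAP or b == GAP:
            side = "a" if a == GAP else "b"
            if run == side:
                runlen += 1
            else:
                if run is not None:
                    total += affine_run_cost(runlen, g, x)
                run, runlen = side, 1
        else:
            if run is not None:
                total += affine_run_cost(runlen, g, x)
                run, runlen = None, 0
            total += score(a, b)
    if run is not None:
        total += affine_run_cost(runlen, g, x)
    return total


def enumerate_global_best(a: str, b: str, score, g: float, x: float) -> float:
    """Maximum global alignment score by exhaustive enumeration of every
    gapped alignment of ``a`` and ``b`` (no gap-gap columns), carrying the
    affine run cost incrementally."""
    la, lb = len(a), len(b)
    best = float("-inf")

    def rec(i: int, j: int, acc: float, open_run: str | None) -> None:
        nonlocal best
        if i == la and j == lb:
            if acc > best:
                best = acc
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, acc + score(a[i], b[j]), None)
        if i < la:  # consume a[i] against a gap in b
            cost = x if open_run == "b" else g + x
            rec(i + 1, j, acc + cost, "b")
        if j < lb:  # consume b[j] against a gap in a
            cost = x if open_run == "a" else g + x
            rec(i, j + 1, acc + cost, "a")

    rec(0, 0, 0.0, None)
    return best


def enumerate_profile_best(
    cols_a: list[tuple[str, ...]],
    cols_b: list[tuple[str, ...]],
    score,
    g: float,
    x: float,
) -> float:
    """Maximum profile-profile alignment score by exhaustive enumeration.

    Column-pair score is the mean over cross row pairs of the substitution
    score, pairs involving an existing gap scoring 0; a new gap run of
    length n costs g + n*x once, unscaled by profile size.
    """
    ka = len(cols_a[0]) if cols_a else 0
    kb = len(cols_b[0]) if cols_b else 0

    def col_score(ca: tuple[str, ...], cb: tuple[str, ...]) -> float:
        s = 0.0
        for r1 in ca:
            for r2 in cb:
                if r1 != GAP and r2 != GAP:
                    s += score(r1, r2)
        return s / (ka * kb)

    la, lb = len(cols_a), len(cols_b)
    best = float("-inf")

    def rec(i: int, j: int, acc: float, open_run: str | None) -> None:
        nonlocal best
        if i == la and j == lb:
            if acc > best:
                best = acc
            return
        if i < la and j < lb:
            rec(i + 1, j + 1, acc + col_score(cols_a[i], cols_b[j]), None)
        if i < la:
            cost = x if open_run == "b" else g + x
            rec(i + 1, j, acc + cost, "b")
        if j < lb:
            cost = x if open_run == "a" else g + x
            rec(i, j + 1, acc + cost, "a")

    rec(0, 0, 0.0, None)
    return best


def wspm_oracle(rows: list[str], weights, score, g: float, x: float) -> float:
    """Weighted sum-of-pairs by scoring every pair's projection from
    scratch."""
    total = 0.0
    for i, j in combinations(range(len(rows)), 2):
        total += weights[i] * weights[j] * score_pairwise_rows(
            rows[i], rows[j], score, g, x
        )
    return total


def residue_ordinal_map(rows: list[str]) -> list[dict[int, int]]:
    """Per row: alignment column -> residue ordinal."""
    out = []
    for row in rows:
        d = {}
        k = 0
        for c, ch in enumerate(row):
            if ch != GAP:
                d[c] = k
                k += 1
        out.append(d)
    return out


def sps_oracle(test_rows: list[str], ref_rows: list[str]) -> float:
    """SPS by brute-force enumeration of every reference residue pair."""
    ref_ord = residue_ordinal_map(ref_rows)
    test_ord = residue_ordinal_map(test_rows)
    test_col = [
        {o: c for c, o in d.items()} for d in test_ord
    ]
    total = matched = 0
    L = len(ref_rows[0])
    for c in range(L):
        present = [
            (i, ref_ord[i][c]) for i in range(len(ref_rows)) if c in ref_ord[i]
        ]
        for (i, oi), (j, oj) in combinations(present, 2):
            total += 1
            if test_col[i][oi] == test_col[j][oj]:
                matched += 1
    return matched / total


def cs_oracle(test_rows: list[str], ref_rows: list[str]) -> float:
    """CS by per-column brute force: a reference column counts if its full
    residue-ordinal tuple (gaps included) appears as a test column."""
    ref_ord = residue_ordinal_map(ref_rows)
    test_ord = residue_ordinal_map(test_rows)

    def col_tuple(ords, c):
        return tuple(d.get(c, -1) for d in ords)

    test_cols = {
        col_tuple(test_ord, c) for c in range(len(test_rows[0]))
    }
    hits = sum(
        1 for c in range(len(ref_rows[0])) if col_tuple(ref_ord, c) in test_cols
    )
    return hits / len(ref_rows[0])
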