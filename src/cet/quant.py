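"""Exactly-specified quantification formulas.

- :func:`ddct` — relative qPCR expression by the 2^-ddCt method: per sample,
  dCt = Ct_target - Ct_reference (technical replicates averaged on the Ct
  scale first), ddCt = dCt_sample - dCt_calibrator, fold = 2^-ddCt.
- :func:`quantify_disaccharides` — stable-isotope internal-standard
  quantification of HS disaccharides: amount = (light area / heavy area) x
  standard pmol (default 20 pmol of each [13C6]aniline-tagged standard),
  normalized to total protein and expressed as percent of total.
- :func:`pairwise_identity_similarity` — percent identity and percent
  similarity (BLOSUM62 score > 0, identities included) from a global
  pairwise alignment with affine gaps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
VALID_AA = AA20 | {"X"}


# ---------------------------------------------------------------------------
# 2^-ddCt
# ---------------------------------------------------------------------------


def ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
) -> pd.DataFrame:
    """Relative expression per sample by the 2^-ddCt method.

    ``ct_table`` columns: sample, gene, ct (one row per technical
    replicate).  Replicate Cts are averaged (arithmetic mean on the Ct
    scale) before differencing.  Non-finite Cts are dropped with a warning.
    Returns one row per sample: mean/SD Cts, dCt, ddCt and fold change;
    the calibrator's own fold change is 1 by construction.
    """
    required = {"sample", "gene", "ct"}
    missing = required - set(ct_table.columns)
    if missing:
        raise ValueError(f"ct_table missing columns: {sorted(missing)}")
    d = ct_table.copy()
    bad = ~np.isfinite(d["ct"].to_numpy(dtype=float))
    if bad.any():
        import warnings

        warnings.warn(f"dropping {int(bad.sum())} non-finite Ct rows", stacklevel=2)
        d = d[~bad]
    genes = set(d["gene"])
    if reference not in genes:
        raise ValueError(f"reference gene {reference!r} not in table")
    if target not in genes:
        raise ValueError(f"target gene {target!r} not in table")

    agg = d.groupby(["sample", "gene"])["ct"].agg(["mean", "std", "size"])
    samples = sorted(d["sample"].unique())
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")
    rows = []
    for s in samples:
        try:
            ct_t = agg.loc[(s, target), "mean"]
            ct_r = agg.loc[(s, reference), "mean"]
        except KeyError as exc:
            raise ValueError(f"sample {s!r} missing target or reference Cts") from exc
        rows.append({"sample": s, "ct_target_mean": ct_t,
                     "ct_target_sd": agg.loc[(s, target), "std"],
                     "ct_reference_mean": ct_r, "dct": ct_t - ct_r})
    out = pd.DataFrame(rows).set_index("sample")
    out["ddct"] = out["dct"] - out.loc[calibrator, "dct"]
    out["fold_change"] = 2.0 ** (-out["ddct"])
    return out.reset_index()


# ---------------------------------------------------------------------------
# Disaccharide quantification
# ---------------------------------------------------------------------------


def quantify_disaccharides(
    peak_table: pd.DataFrame,
    standard_pmol: float = 20.0,
    protein_ug: float | None = None,
) -> pd.DataFrame:
    """Internal-standard quantification of disaccharide peak areas.

    ``peak_table`` columns: code (D-notation, e.g. D0A0, D0S6, D2S6),
    light_area ([12C6]aniline-tagged sample channel), heavy_area ([13C6]
    internal standard channel).  amount_pmol = light/heavy x standard_pmol;
    percent is over the quantifiable codes; amount_per_ug is reported when
    ``protein_ug`` is given (BCA-normalized composition).  Codes with zero
    heavy-channel area are flagged unquantifiable (NaN amounts).
    """
    required = {"code", "light_area", "heavy_area"}
    missing = required - set(peak_table.columns)
    if missing:
        raise ValueError(f"peak_table missing columns: {sorted(missing)}")
    if protein_ug is not None and protein_ug <= 0:
        raise ValueError("protein_ug must be > 0")
    d = peak_table.copy()
    if (d["light_area"] < 0).any() or (d["heavy_area"] < 0).any():
        raise ValueError("peak areas must be >= 0")
    quantifiable = d["heavy_area"] > 0
    if not quantifiable.any():
        raise ValueError("no quantifiable codes: all heavy-channel areas are zero")
    d["quantifiable"] = quantifiable
    d["amount_pmol"] = np.where(
        quantifiable, d["light_area"] / d["heavy_area"].where(quantifiable) * standard_pmol, np.nan)
    total = d.loc[quantifiable, "amount_pmol"].sum()
    d["percent"] = np.where(quantifiable & (total > 0), 100.0 * d["amount_pmol"] / total, np.nan)
    if protein_ug is not None:
        d["amount_pmol_per_ug"] = d["amount_pmol"] / protein_ug
    return d


# ---------------------------------------------------------------------------
# Pairwise identity / similarity
# ---------------------------------------------------------------------------


@dataclass
class AlignmentStats:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    similarity_pct: float
    alignment_length: int
    gap_count: int


def _blosum62_x0():
    """BLOSUM62 with every X pairing scored 0 (unknown residues are neutral)."""
    m = substitution_matrices.load("BLOSUM62")
    arr = np.array(m)
    letters = m.alphabet
    xi = letters.index("X")
    arr[xi, :] = 0.0
    arr[:, xi] = 0.0
    return substitution_matrices.Array(alphabet=letters, dims=2, data=arr)


_MATRIX = _blosum62_x0()


def _validate(seq: str, which: str) -> str:
    if not seq:
        raise ValueError(f"empty sequence {which}")
    s = seq.upper()
    for i, c in enumerate(s):
        if c not in VALID_AA and c != "-":
            raise ValueError(f"unknown character {c!r} at position {i} of sequence {which}")
    return s


def global_align(seq_a: str, seq_b: str, gap_open: float = 10.0, gap_extend: float = 0.5):
    """Optimal global alignment under BLOSUM62 with affine gaps.

    A gap of length L costs gap_open + (L - 1) * gap_extend (the opening
    penalty includes the first gapped position).  Returns the aligned
    strings with '-' for gaps, and the optimal score.
    """
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = _MATRIX
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    aln = aligner.align(seq_a, seq_b)[0]
    a, b = str(aln[0]), str(aln[1])
    return a, b, float(aln.score)


def pairwise_identity_similarity(
    seq_a: str,
    seq_b: str,
    prealigned: bool = False,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    denominator: str = "aligned",
) -> AlignmentStats:
    """Percent identity and similarity of two protein sequences.

    If ``prealigned``, the inputs (with '-' gaps) are scored as given;
    otherwise a global alignment is computed.  Identity counts identical
    residue columns; similarity counts columns that are identical or whose
    BLOSUM62 score is positive.  ``denominator`` is "aligned" (columns where
    both sequences have residues — the common convention, default) or
    "all" (every alignment column).
    """
    a = _validate(seq_a, "a")
    b = _validate(seq_b, "b")
    if denominator not in ("aligned", "all"):
        raise ValueError("denominator must be 'aligned' or 'all'")
    if prealigned:
        if len(a) != len(b):
            raise ValueError("prealigned sequences must have equal length")
        score = _score_alignment(a, b, gap_open, gap_extend)
    else:
        if "-" in a or "-" in b:
            raise ValueError("unaligned input must not contain gaps")
        a, b, score = global_align(a, b, gap_open, gap_extend)

    ident = simil = both = 0
    gaps = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            gaps += 1
            continue
        both += 1
        if ca == cb:
            ident += 1
            simil += 1
        elif _MATRIX[ca, cb] > 0:
            simil += 1
    denom = both if denominator == "aligned" else len(a)
    if denom == 0:
        raise ValueError("no aligned residue columns")
    return AlignmentStats(a, b, score, 100.0 * ident / denom, 100.0 * simil / denom,
                          len(a), gaps)


def _score_alignment(a: str, b: str, gap_open: float, gap_extend: float) -> float:
    """Affine-gap score of a given alignment (open includes first position)."""
    score = 0.0
    in_gap_a = in_gap_b = False
    for ca, cb in zip(a, b):
        if ca == "-" and cb == "-":
            raise ValueError("double-gap column in alignment")
        if ca == "-":
            score -= gap_open if not in_gap_a else gap_extend
            in_gap_a, in_gap_b = True, False
        elif cb == "-":
            score -= gap_open if not in_gap_b else gap_extend
            in_gap_b, in_gap_a = True, False
        else:
            score += float(_MATRIX[ca, cb])
            in_gap_a = in_gap_b = False
    return score
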