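"""Position-weight-matrix construction, log-odds scanning, ZOOPS-EM motif
discovery and motif enrichment statistics.

The X-box bound by RFX-family factors is a ~14-bp inverted repeat; the
default discovery width and the default seed consensus reflect that. A
promoter "contains an X-box" when a scan hit on either strand reaches the
configured fraction of the PWM's maximum achievable log2-odds score.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G


def encode(seq: str) -> np.ndarray:
    """Encode ACGT(N) as int8; any non-ACGT base becomes -1 (skipped)."""
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(len(arr), -1, dtype=np.int8)
    for b, i in _IDX.items():
        out[arr == ord(b)] = i
    return out


@dataclass
class PWM:
    """Column-stochastic base probabilities with a scanning threshold."""

    probs: np.ndarray  # 4 x L
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.0
    score_threshold: Optional[float] = None  # bits; None -> 0.6 * max score

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError("PWM must be 4 x L with L >= 4")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.probs) - np.log2(self.background)[:, None]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def effective_threshold(self) -> float:
        if self.score_threshold is not None:
            return self.score_threshold
        return 0.6 * max(self.max_score, 0.0)

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.probs.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(probs=self.probs[_COMP][:, ::-1], background=self.background,
                   pseudocount=self.pseudocount, score_threshold=self.score_threshold)

    def inverted_repeat_score(self) -> float:
        """Mean column-wise Pearson r between the PWM and its reverse
        complement; 1.0 for a perfectly palindromic motif."""
        rc = self.reverse_complement().probs
        rs = []
        for j in range(self.width):
            a, b = self.probs[:, j], rc[:, j]
            if a.std() < 1e-12 or b.std() < 1e-12:
                rs.append(1.0 if np.allclose(a, b) else 0.0)
            else:
                rs.append(float(np.corrcoef(a, b)[0, 1]))
        return float(np.mean(rs))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, index=list(ALPHABET),
                          columns=[f"pos{j + 1}" for j in range(self.width)])
        df.index.name = "base"
        return df


@dataclass(frozen=True)
class MotifHit:
    seq_id: str
    offset: int  # forward-strand 0-based start
    strand: str
    score: float


def build_pwm(sites: Sequence[str], pseudocount: float = 0.5,
              background: Optional[Sequence[float]] = None) -> PWM:
    """Count matrix -> probabilities with an additive pseudocount.

    Column j probability of base b is (count + pseudocount/4) / (n +
    pseudocount).
    """
    if not sites:
        raise ValueError("no sites")
    L = len(sites[0])
    if any(len(s) != L for s in sites):
        raise ValueError("sites must share one length")
    counts = np.zeros((4, L))
    for s in sites:
        enc = encode(s)
        if (enc < 0).any():
            raise ValueError(f"site {s!r} contains non-ACGT characters")
        counts[enc, np.arange(L)] += 1
    probs = (counts + pseudocount / 4.0) / (len(sites) + pseudocount)
    bg = np.asarray(background if background is not None else np.full(4, 0.25))
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


def _window_scores(enc: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score every window; windows containing a skipped base score -inf."""
    L = log_odds.shape[1]
    n = len(enc) - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        col = enc[j : j + n]
        valid = col >= 0
        scores[valid] += log_odds[col[valid], j]
        bad |= ~valid
    scores[bad] = -np.inf
    return scores


def scan_pwm(sequence: str, pwm: PWM, seq_id: str = "seq",
             threshold: Optional[float] = None) -> List[MotifHit]:
    """Log2-odds scan of both strands; hits reported in forward coordinates.

    The reverse strand is scored by scanning with the reverse-complement
    matrix, so a hit at forward offset j on strand '-' corresponds to the
    motif read 3'->5' at that window. Sequences shorter than the motif
    yield no hits; windows containing N are skipped.
    """
    thr = pwm.effective_threshold if threshold is None else threshold
    enc = encode(sequence)
    hits: List[MotifHit] = []
    for strand, matrix in (("+", pwm.log_odds),
                           ("-", pwm.reverse_complement().log_odds)):
        scores = _window_scores(enc, matrix)
        for j in np.flatnonzero(scores >= thr):
            hits.append(MotifHit(seq_id=seq_id, offset=int(j), strand=strand,
                                 score=float(scores[j])))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


# ---------------------------------------------------------------------------
# ZOOPS EM discovery
# ---------------------------------------------------------------------------

@dataclass
class EMResult:
    pwm: PWM
    gamma: float  # occurrence probability
    log_likelihood: float  # raw data log-likelihood at convergence
    ll_trajectory: List[float]  # penalized EM objective; non-decreasing
    posteriors: List[dict]  # per sequence: {"absent": w, "sites": [(offset, strand, w)]}


def _background_freqs(encoded: Sequence[np.ndarray]) -> np.ndarray:
    counts = np.ones(4)  # +1 smoothing
    for enc in encoded:
        v = enc[enc >= 0]
        counts += np.bincount(v, minlength=4)
    return counts / counts.sum()


def discover_motif_em(sequences: Sequence[str], width: int = 14,
                      n_restarts: int = 5, seed: int = 0,
                      max_iter: int = 500, tol: float = 1e-6,
                      pseudocount: float = 0.5,
                      max_shift: int = 3) -> EMResult:
    """ZOOPS (zero-or-one occurrence per sequence) EM motif discovery.

    E-step: per sequence, posterior over {absent} + every (offset, strand)
    site placement under the current PWM, background and occurrence prior.
    M-step: pseudocounted expected-count PWM update and occurrence-rate
    update. Runs to log-likelihood change < `tol` or `max_iter` iterations;
    the best of `n_restarts` (each initialized from a randomly chosen data
    window) is returned, after refining against phase-shifted restarts of
    the winning matrix (EM's classic local optimum). The reported
    trajectory is the winning run's penalized objective, which is
    non-decreasing across its iterations.
    """
    if len(sequences) < 10:
        raise ValueError("need at least 10 sequences")
    if any(len(s) < width for s in sequences):
        raise ValueError("width exceeds the shortest sequence length")
    encoded = [encode(s) for s in sequences]
    bg = _background_freqs(encoded)
    log_bg = np.log(bg)
    # per-sequence background log-likelihood (skipped bases contribute 0)
    bg_ll = np.array([log_bg[enc[enc >= 0]].sum() for enc in encoded])
    rng = np.random.default_rng(seed)

    def run_em(theta0: np.ndarray) -> EMResult:
        theta = theta0
        gamma = 0.5
        traj: List[float] = []
        posts: List[dict] = []
        ll = -np.inf
        for _it in range(max_iter):
            theta_new, gamma_new, ll, posts = _em_step(
                encoded, theta, gamma, bg, bg_ll, width, pseudocount)
            # the pseudocounted M-step ascends ll + (pc/4) * sum log(theta)
            prior = (pseudocount / 4.0) * np.log(np.maximum(theta, 1e-300)).sum()
            traj.append(ll + prior)
            if len(traj) > 1 and abs(traj[-1] - traj[-2]) < tol:
                theta, gamma = theta_new, gamma_new
                break
            theta, gamma = theta_new, gamma_new
        pwm = PWM(probs=theta, background=bg)
        return EMResult(pwm=pwm, gamma=gamma, log_likelihood=float(ll),
                        ll_trajectory=traj, posteriors=posts)

    best: Optional[EMResult] = None
    for _ in range(max(1, n_restarts)):
        result = run_em(_init_theta(encoded, width, rng))
        if best is None or result.log_likelihood > best.log_likelihood:
            best = result
    # phase-shift refinement: restart EM from column-shifted variants of the
    # winning matrix and keep any strictly better optimum
    improved = True
    while improved and max_shift > 0:
        improved = False
        for shift in [s for k in range(1, max_shift + 1) for s in (-k, k)]:
            cand = run_em(_shift_theta(best.pwm.probs, shift, bg))
            if cand.log_likelihood > best.log_likelihood + tol:
                best = cand
                improved = True
                break
    return best


def _shift_theta(theta: np.ndarray, shift: int, bg: np.ndarray) -> np.ndarray:
    """Shift PWM columns by `shift` positions, padding with background."""
    width = theta.shape[1]
    out = np.tile(bg[:, None], (1, width))
    if shift > 0:
        out[:, shift:] = theta[:, : width - shift]
    else:
        out[:, : width + shift] = theta[:, -shift:]
    return out


def _init_theta(encoded: Sequence[np.ndarray], width: int,
                rng: np.random.Generator) -> np.ndarray:
    for _ in range(100):
        i = rng.integers(0, len(encoded))
        enc = encoded[i]
        j = rng.integers(0, len(enc) - width + 1)
        window = enc[j : j + width]
        if (window >= 0).all():
            theta = np.full((4, width), 0.1)
            theta[window, np.arange(width)] = 0.7
            return theta / theta.sum(axis=0)
    return np.full((4, width), 0.25)


def _site_loglik(enc: np.ndarray, log_theta: np.ndarray, log_bg: np.ndarray,
                 bg_ll_total: float) -> np.ndarray:
    """Log-likelihood of the sequence with a site at each forward offset:
    background everywhere except the window, which is scored by the PWM."""
    L = log_theta.shape[1]
    n = len(enc) - L + 1
    out = np.full(n, -np.inf)
    scores = np.zeros(n)
    bgpart = np.zeros(n)
    bad = np.zeros(n, dtype=bool)
    for j in range(L):
        col = enc[j : j + n]
        valid = col >= 0
        scores[valid] += log_theta[col[valid], j]
        bgpart[valid] += log_bg[col[valid]]
        bad |= ~valid
    res = bg_ll_total - bgpart + scores
    res[bad] = -np.inf
    return res


def _em_step(encoded, theta, gamma, bg, bg_ll, width, pseudocount):
    log_theta = np.log(np.maximum(theta, 1e-300))
    log_theta_rc = log_theta[_COMP][:, ::-1]
    log_bg = np.log(bg)
    exp_counts = np.full((4, width), pseudocount / 4.0)
    exp_occurrence = 0.0
    ll_total = 0.0
    posts: List[dict] = []
    for i, enc in enumerate(encoded):
        n = len(enc) - width + 1
        fwd = _site_loglik(enc, log_theta, log_bg, bg_ll[i])
        rev = _site_loglik(enc, log_theta_rc, log_bg, bg_ll[i])
        site_ll = np.concatenate([fwd, rev])
        prior_site = np.log(max(gamma, 1e-300)) - np.log(2 * n)
        terms = np.concatenate([[np.log(max(1 - gamma, 1e-300)) + bg_ll[i]],
                                prior_site + site_ll])
        m = terms.max()
        w = np.exp(terms - m)
        total = w.sum()
        ll_total += m + np.log(total)
        w /= total
        posts.append({"absent": float(w[0]),
                      "sites": [(int(j % n), "+" if j < n else "-", float(w[1 + j]))
                                for j in np.flatnonzero(w[1:] > 1e-3)]})
        exp_occurrence += 1.0 - w[0]
        wf = w[1 : 1 + n]
        wr = w[1 + n :]
        for j in range(width):
            col = enc[j : j + n]
            valid = col >= 0
            np.add.at(exp_counts[:, j], col[valid], wf[valid])
            # reverse-strand site: position j of the motif aligns with
            # forward position (width-1-j), complemented
            col2 = enc[width - 1 - j : width - 1 - j + n]
            valid2 = col2 >= 0
            np.add.at(exp_counts[:, j], _COMP[col2[valid2]], wr[valid2])
    theta_new = exp_counts / exp_counts.sum(axis=0)
    gamma_new = float(np.clip(exp_occurrence / len(encoded), 1e-6, 1 - 1e-6))
    return theta_new, gamma_new, float(ll_total), posts


# ---------------------------------------------------------------------------
# Enrichment and positional summaries
# ---------------------------------------------------------------------------

def motif_enrichment(fg_genes: Set[str], bg_genes: Set[str],
                     promoter_seqs: Dict[str, str], pwm: PWM) -> dict:
    """Hypergeometric test of motif-containing promoters, foreground vs
    background (disjoint sets).

    Returns the 2x2 counts and the one-sided (enrichment) upper-tail p.
    """
    if not fg_genes:
        raise ValueError("empty foreground")
    if fg_genes & bg_genes:
        raise ValueError("foreground and background must be disjoint")

    def has_motif(g: str) -> bool:
        seq = promoter_seqs.get(g, "")
        return bool(scan_pwm(seq, pwm, seq_id=g))

    fg_with = sum(has_motif(g) for g in sorted(fg_genes))
    bg_with = sum(has_motif(g) for g in sorted(bg_genes))
    N = len(fg_genes) + len(bg_genes)
    K = fg_with + bg_with
    n = len(fg_genes)
    p = float(stats.hypergeom.sf(fg_with - 1, N, K, n))
    return {"fg_with": fg_with, "fg_total": len(fg_genes),
            "bg_with": bg_with, "bg_total": len(bg_genes),
            "p_enrichment": min(1.0, p)}


def positional_profile(hits: Sequence[MotifHit], anchors: Dict[str, int],
                       motif_width: int, bin_width: int = 25,
                       strands: Optional[Dict[str, str]] = None) -> pd.DataFrame:
    """Histogram of motif-hit centers relative to per-sequence anchors.

    `anchors` maps seq_id to the anchor coordinate in the same forward
    frame as the hit offsets (TSS position or peak-summit offset). When
    `strands` marks a sequence's gene as '-', the sign is flipped so
    distances are transcription-aware.
    """
    dists = []
    for h in hits:
        if h.seq_id not in anchors:
            continue
        center = h.offset + motif_width // 2
        d = center - anchors[h.seq_id]
        if strands is not None and strands.get(h.seq_id) == "-":
            d = -d
        dists.append(d)
    if not dists:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    lo = (min(dists) // bin_width) * bin_width
    hi = ((max(dists) // bin_width) + 1) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, _ = np.histogram(dists, bins=edges)
    return pd.DataFrame({"bin_start": edges[:-1], "bin_end": edges[1:],
                         "count": counts})
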