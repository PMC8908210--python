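"""Synthetic study generator with planted ground truth.

Every input the pipeline consumes can be generated here at reduced scale:
an 876 nt inverted-repeat construct, a transcript set with planted
near-match off-target sites, small-RNA read sets peaked at 21 nt with
positional hotspots, six-line three-replicate expression and metabolite
matrices with a genetic-background split and planted differential
features, and a gene-to-pathway annotation with one over-drawn term.
The returned :class:`PlantedTruth` makes every planted signal verifiable
by direct recomputation on the emitted data.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import CONVENTIONAL, StudyDesign
from .mocklib import DsRNAConstruct, hamming_distance
from .stats import OmicsMatrix, parse_comparison

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class OfftargetSite:
    transcript_id: str
    position: int  # 0-based start of the embedded k-mer on the transcript
    k: int
    hamming: int  # substitutions applied to the construct window
    kmer_start: int  # 0-based start of the source window on the construct


@dataclass
class PlantedTruth:
    """Ground truth of everything the generators planted."""

    offtarget_sites: list[OfftargetSite] = field(default_factory=list)
    de_features: dict[str, dict[str, float]] = field(default_factory=dict)
    enriched_terms: set[str] = field(default_factory=set)


def _random_sequence(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


# ---------------------------------------------------------------------------
# sequences


def gen_dsrna(length: int, gc_fraction: float = 0.5, seed: int = 0) -> DsRNAConstruct:
    """Random inverted-repeat-style construct of exactly ``length`` nt.

    876 nt is the reference construct size.  Lengths below 24 cannot host
    even one mock k-mer and are rejected.
    """
    if length < 24:
        raise ValueError("construct length must be >= 24 (largest mock k-mer)")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    return DsRNAConstruct(f"dsRNA_{length}", _random_sequence(rng, length, gc_fraction))


def gen_transcriptome(
    n_transcripts: int,
    length_range: tuple[int, int],
    dsrna: DsRNAConstruct,
    planted: Sequence[tuple[int, int]] = (),
    seed: int = 0,
    gc_fraction: float = 0.5,
) -> tuple[list[tuple[str, str]], PlantedTruth]:
    """Random transcripts, each planted spec embedding one construct
    window with an exact number of substitutions.

    ``planted`` is a list of ``(k, hamming)`` pairs; spec *i* is embedded
    in transcript *i*.  The applied Hamming distance is re-verified
    against the emitted transcript before returning.
    """
    lo, hi = length_range
    if lo > hi or lo < 24:
        raise ValueError("length_range must satisfy 24 <= lo <= hi")
    if len(planted) > n_transcripts:
        raise ValueError("more planted sites than transcripts")
    rng = np.random.default_rng(seed)
    truth = PlantedTruth()
    records: list[tuple[str, str]] = []
    for i in range(n_transcripts):
        tid = f"tx{i:04d}"
        tlen = int(rng.integers(lo, hi + 1))
        seq = list(_random_sequence(rng, tlen, gc_fraction))
        if i < len(planted):
            k, ham = planted[i]
            if not 21 <= k <= 24:
                raise ValueError("planted k must lie in 21..24")
            if ham < 0 or ham > k:
                raise ValueError("planted hamming must lie in 0..k")
            if tlen < k:
                raise ValueError("transcript shorter than planted k-mer")
            ks = int(rng.integers(0, dsrna.length - k + 1))
            window = list(dsrna.sequence[ks : ks + k])
            for pos in rng.choice(k, size=ham, replace=False):
                alternatives = [b for b in "ACGT" if b != window[pos]]
                window[pos] = alternatives[int(rng.integers(0, 3))]
            tpos = int(rng.integers(0, tlen - k + 1))
            seq[tpos : tpos + k] = window
            emitted = "".join(seq)
            applied = hamming_distance(
                dsrna.sequence[ks : ks + k], emitted[tpos : tpos + k]
            )
            assert applied == ham, "planted distance does not match applied edits"
            truth.offtarget_sites.append(OfftargetSite(tid, tpos, k, ham, ks))
        records.append((tid, "".join(seq)))
    return records, truth


def gen_srna_reads(
    dsrna: DsRNAConstruct,
    n_reads: int,
    length_weights: Mapping[int, float] | None = None,
    hotspots: Sequence[tuple[int, float]] | None = None,
    background_fraction: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Small-RNA reads drawn from the construct plus random background.

    Non-background reads are exact substrings of either strand; their
    first-base positions (on the chosen strand's own coordinates) are
    drawn from the ``hotspots`` distribution, or uniformly when none are
    given.  Read lengths follow ``length_weights`` (default: the 21 nt
    dominated shape typical of Dicer products: 70% mass at 21 nt).
    """
    if length_weights is None:
        length_weights = {20: 0.1, 21: 0.7, 22: 0.1, 23: 0.05, 24: 0.05}
    lengths = sorted(length_weights)
    weights = np.array([length_weights[l] for l in lengths], dtype=float)
    if any(not 18 <= l <= 30 for l in lengths):
        raise ValueError("read lengths must lie in 18..30")
    if np.any(weights < 0) or weights.sum() == 0:
        raise ValueError("length weights must be nonnegative and not all zero")
    weights = weights / weights.sum()
    if not 0 <= background_fraction <= 1:
        raise ValueError("background_fraction must lie in [0, 1]")
    max_start = dsrna.length - min(lengths)
    if hotspots is not None:
        hs_pos = np.array([p for p, _ in hotspots], dtype=int)
        hs_w = np.array([w for _, w in hotspots], dtype=float)
        if np.any(hs_pos < 0) or np.any(hs_pos > max_start):
            raise ValueError("hotspot position out of range for the shortest read")
        if np.any(hs_w < 0) or hs_w.sum() == 0:
            raise ValueError("hotspot weights must be nonnegative, not all zero")
        hs_w = hs_w / hs_w.sum()
    rng = np.random.default_rng(seed)
    n_background = int(round(background_fraction * n_reads))
    n_signal = n_reads - n_background
    strands = {0: dsrna.sequence, 1: dsrna.antisense}
    reads: list[tuple[str, str]] = []
    for i in range(n_signal):
        if hotspots is not None:
            start = int(hs_pos[rng.choice(len(hs_pos), p=hs_w)])
        else:
            start = int(rng.integers(0, max_start + 1))
        # restrict to lengths that fit past the chosen start
        fits = np.array([start + l <= dsrna.length for l in lengths])
        w = weights * fits
        length = lengths[int(rng.choice(len(lengths), p=w / w.sum()))]
        strand = strands[int(rng.integers(0, 2))]
        reads.append((f"read_{i:06d}", strand[start : start + length]))
    for i in range(n_background):
        length = lengths[int(rng.choice(len(lengths), p=weights))]
        reads.append((f"bg_{i:06d}", _random_sequence(rng, length)))
    return reads


# ---------------------------------------------------------------------------
# omics matrices


def _apply_planted(
    design: StudyDesign,
    planted: Mapping[str, tuple[int, float]] | None,
    feature_ids: list[str],
    rng: np.random.Generator,
) -> tuple[dict[str, dict[str, float]], dict[str, dict[str, float]]]:
    """Resolve planted specs into (truth, per-line log2 shifts).

    Effects alternate sign so up- and down-regulation are both exercised;
    the signed effect is applied to the *first* line of the comparison.
    """
    truth: dict[str, dict[str, float]] = {}
    shifts: dict[str, dict[str, float]] = {}  # line -> feature -> log2 shift
    if not planted:
        return truth, shifts
    cursor = 0
    for comp, (n_de, log2_effect) in planted.items():
        line_a, line_b = parse_comparison(comp)
        for line in (line_a, line_b):
            if line not in design.roles:
                raise ValueError(f"planted comparison names unknown line {line!r}")
        if cursor + n_de > len(feature_ids):
            raise ValueError("not enough features for the planted effects")
        chosen = feature_ids[cursor : cursor + n_de]
        cursor += n_de
        comp_truth = {}
        for j, feat in enumerate(chosen):
            effect = log2_effect if j % 2 == 0 else -log2_effect
            comp_truth[feat] = effect
            shifts.setdefault(line_a, {})[feat] = effect
        truth[f"{line_a}/{line_b}"] = comp_truth
    return truth, shifts


def gen_expression_study(
    design: StudyDesign,
    n_features: int = 1000,
    planted: Mapping[str, tuple[int, float]] | None = None,
    sigma_log2: float = 0.25,
    baseline_log2_range: tuple[float, float] = (3.0, 10.0),
    background_fraction: float = 0.1,
    background_log2_effect: float = 3.0,
    noise_model: str = "lognormal",
    dispersion: float = 0.1,
    seed: int = 0,
) -> tuple[OmicsMatrix, PlantedTruth]:
    """FPKM-like expression matrix with planted differential genes.

    The default noise model is log-normal: log2 intensities are baseline
    + shift + N(0, sigma_log2).  ``background_fraction`` of features get
    an extra shift in the conventionally bred lines, emulating the
    genetic-background separation seen between breeding programs (this
    is what makes PCA/clustering split conventional lines from GE lines
    plus parent).  ``noise_model="negbin"`` draws negative-binomial
    counts with the same mean structure instead.
    """
    rng = np.random.default_rng(seed)
    features = [f"gene{i:05d}" for i in range(n_features)]
    de_truth, shifts = _apply_planted(design, planted, features, rng)

    mu = rng.uniform(*baseline_log2_range, size=n_features)
    n_bg = int(round(background_fraction * n_features))
    bg_idx = rng.choice(n_features, size=n_bg, replace=False) if n_bg else np.array([], int)
    bg_sign = rng.choice([-1.0, 1.0], size=n_bg)

    columns = {}
    conventional = set(design.lines_with_role(CONVENTIONAL))
    for line in design.lines:
        base = mu.copy()
        for feat, eff in shifts.get(line, {}).items():
            base[features.index(feat)] += eff
        if line in conventional and n_bg:
            base[bg_idx] += bg_sign * background_log2_effect
        for rep in range(1, design.replicates_per_line + 1):
            if noise_model == "lognormal":
                vals = 2.0 ** (base + rng.normal(0.0, sigma_log2, size=n_features))
            elif noise_model == "negbin":
                mean = 2.0**base
                r = 1.0 / max(dispersion, 1e-9)
                vals = rng.negative_binomial(r, r / (r + mean)).astype(float)
            else:
                raise ValueError(f"unknown noise_model: {noise_model!r}")
            columns[f"{line}_{rep}"] = vals
    data = pd.DataFrame(columns, index=features)
    truth = PlantedTruth(de_features=de_truth)
    return OmicsMatrix(data, design), truth


def gen_metabolome_study(
    design: StudyDesign,
    n_features: int = 400,
    planted: Mapping[str, tuple[int, float]] | None = None,
    missing_rate: float = 0.0,
    sigma_log2: float = 0.25,
    baseline_log2_range: tuple[float, float] = (10.0, 20.0),
    background_fraction: float = 0.1,
    background_log2_effect: float = 3.0,
    seed: int = 0,
) -> tuple[OmicsMatrix, PlantedTruth]:
    """Metabolite intensity matrix: log-normal peak areas with planted
    differential metabolites and missing-completely-at-random cells."""
    if not 0 <= missing_rate <= 1:
        raise ValueError("missing_rate must lie in [0, 1]")
    matrix, truth = gen_expression_study(
        design,
        n_features=n_features,
        planted=planted,
        sigma_log2=sigma_log2,
        baseline_log2_range=baseline_log2_range,
        background_fraction=background_fraction,
        background_log2_effect=background_log2_effect,
        seed=seed,
    )
    data = matrix.data.rename(index=lambda f: f.replace("gene", "met"))
    truth.de_features = {
        comp: {f.replace("gene", "met"): e for f, e in feats.items()}
        for comp, feats in truth.de_features.items()
    }
    if missing_rate > 0:
        rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
        mask = rng.random(data.shape) < missing_rate
        data = data.mask(mask)
    return OmicsMatrix(data, design), truth


# ---------------------------------------------------------------------------
# annotation


def gen_annotation(
    feature_ids: Sequence[str],
    n_terms: int = 20,
    planted_term: tuple[str, float] | None = None,
    target_list: Sequence[str] | None = None,
    term_size_range: tuple[int, int] = (5, 50),
    seed: int = 0,
) -> tuple[dict[str, set[str]], PlantedTruth]:
    """Random flat-term annotation with one optionally over-drawn term.

    The planted term draws ``overdraw`` times its expected number of
    members from ``target_list`` (the feature list later tested for
    enrichment), making it the most over-represented term by
    construction.
    """
    features = list(feature_ids)
    lo, hi = term_size_range
    if hi > len(features):
        raise ValueError("term sizes cannot exceed the number of features")
    rng = np.random.default_rng(seed)
    annotation: dict[str, set[str]] = {}
    truth = PlantedTruth()
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = set(rng.choice(features, size=size, replace=False))
        annotation[f"term{i:03d}"] = members
    if planted_term is not None:
        term_id, overdraw = planted_term
        if target_list is None:
            raise ValueError("planted_term requires target_list")
        lst = [f for f in target_list if f in set(features)]
        size = int(rng.integers(lo, hi + 1))
        expected = size * len(lst) / len(features)
        n_hits = min(len(lst), size, max(1, int(round(overdraw * expected))))
        hits = set(rng.choice(lst, size=n_hits, replace=False))
        rest_pool = [f for f in features if f not in set(lst)]
        rest = set(rng.choice(rest_pool, size=size - n_hits, replace=False))
        annotation[term_id] = hits | rest
        truth.enriched_terms.add(term_id)
    return annotation, truth
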