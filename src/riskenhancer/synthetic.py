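"""Synthetic inputs with known ground truth for every pipeline stage.

Haplotype panels use a template-copy LD model: variants of a block are
noisy copies of a shared template haplotype, where each entry is resampled
with probability m (keeping the template's allele frequency).  Two copies
with resample probabilities m_u and m_v then have correlation
(1-m_u)(1-m_v), so for a common m the pairwise r^2 within a block is
(1-m)^4 and m = 1 - rho^(1/4) hits a target rho exactly in expectation.
Relative to the template itself (m = 0), a copy with m = 1 - sqrt(rho) has
r^2 = rho.  Blocks are independent, so across-block r^2 has expectation ~0.

All generators take an explicit integer seed and never touch global random
state; a :class:`TruthTable` records what was planted so tests can compare
pipeline output against construction rather than against re-computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .intervals import GenomeSpec, IntervalTrack, TrackSet, write_bed
from .luciferase import (LuciferaseDesign, TrueLuciferaseParams,
                         draw_true_params_from_priors, simulate_luciferase_dataset)
from .panel import HaplotypePanel, write_vcf
from .pwm import BASES, PWM, score_allele_disruption, write_pwms

__all__ = [
    "TruthTable", "simulate_haplotype_panel", "simulate_two_population_panels",
    "generate_biofeature_tracks", "track_covering", "generate_pwm_library",
    "plant_disruptions", "simulate_luciferase_dataset", "LuciferaseDesign",
    "TrueLuciferaseParams", "draw_true_params_from_priors", "write_dataset",
]


@dataclass
class TruthTable:
    """What was planted: proxy pairs, motif disruptions, luciferase truth.

    ``proxy_pairs`` columns: index_id, proxy_id, population, r2_target,
    dual (bool), in_biofeature (bool, set by :func:`track_covering`).
    ``disruptions`` columns: variant_id, pwm, match_allele, disrupt_allele.
    """

    proxy_pairs: pd.DataFrame = field(default_factory=pd.DataFrame)
    disruptions: pd.DataFrame = field(default_factory=pd.DataFrame)
    luciferase: TrueLuciferaseParams | None = None

    def validate_ids(self, panels: list[HaplotypePanel]) -> None:
        """Every planted variant id must exist in at least one panel."""
        known = set()
        for p in panels:
            known |= set(p.variants["id"])
        planted = set()
        if not self.proxy_pairs.empty:
            planted |= set(self.proxy_pairs["index_id"])
            planted |= set(self.proxy_pairs["proxy_id"])
        if not self.disruptions.empty:
            planted |= set(self.disruptions["variant_id"])
        missing = planted - known
        if missing:
            raise ValueError(f"planted ids missing from panels: {sorted(missing)[:5]}")

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if not self.proxy_pairs.empty:
            self.proxy_pairs.to_csv(path.with_suffix(".proxies.tsv"), sep="\t",
                                    index=False)
        if not self.disruptions.empty:
            self.disruptions.to_csv(path.with_suffix(".disruptions.tsv"), sep="\t",
                                    index=False)


def _maf_check(maf_range: tuple[float, float]) -> None:
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie inside (0, 0.5], got {maf_range}")


def _draw_alleles(rng: np.random.Generator, n: int) -> tuple[list[str], list[str]]:
    refs = [BASES[i] for i in rng.integers(0, 4, n)]
    alts = [BASES[(BASES.index(r) + int(rng.integers(1, 4))) % 4] for r in refs]
    return refs, alts


def _copy_template(rng: np.random.Generator, template: np.ndarray, p: float,
                   m: float) -> np.ndarray:
    """Template copy with per-entry resample probability m (marginal freq p)."""
    col = template.copy()
    mask = rng.random(template.shape[0]) < m
    col[mask] = (rng.random(mask.sum()) < p).astype(np.int8)
    return col


def _polymorphic_copy(rng, template, p, m, max_tries=200) -> np.ndarray:
    for _ in range(max_tries):
        col = _copy_template(rng, template, p, m)
        if 0 < col.sum() < col.shape[0]:
            return col
    raise RuntimeError("could not draw a polymorphic column; enlarge the panel "
                       "or the MAF range")


def simulate_haplotype_panel(
    spec: GenomeSpec,
    n_samples: int,
    n_variants: int,
    block_len: int = 50_000,
    within_block_r2: float = 0.8,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    population: str = "POP",
) -> HaplotypePanel:
    """One population's phased panel with block LD structure.

    Variants are placed at distinct positions on the spec's first
    chromosome; variants sharing a position block of ``block_len`` bp are
    copies of one template and achieve pairwise r^2 of ``within_block_r2``
    in expectation, while across blocks r^2 is ~0.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 <= within_block_r2 <= 1.0:
        raise ValueError("within_block_r2 must lie in [0, 1]")
    _maf_check(maf_range)
    rng = np.random.default_rng(seed)
    chrom = spec.chromosomes[0]
    length = spec.length_by_chrom[chrom]
    if n_variants > length:
        raise ValueError("more variants than positions")
    pos0 = np.sort(rng.choice(length, size=n_variants, replace=False))
    blocks = pos0 // block_len
    m = 1.0 - within_block_r2 ** 0.25
    n_hap = 2 * n_samples

    cols = np.empty((n_hap, n_variants), dtype=np.int8)
    for b in np.unique(blocks):
        idx = np.where(blocks == b)[0]
        p = rng.uniform(*maf_range)
        template = (rng.random(n_hap) < p).astype(np.int8)
        while not 0 < template.sum() < n_hap:
            template = (rng.random(n_hap) < p).astype(np.int8)
        for j in idx:
            if within_block_r2 >= 1.0:
                cols[:, j] = template
            else:
                cols[:, j] = _polymorphic_copy(rng, template, p, m)

    refs, alts = _draw_alleles(rng, n_variants)
    variants = pd.DataFrame({
        "id": [f"{population}_v{j}" if population else f"v{j}"
               for j in range(n_variants)],
        "chrom": chrom,
        "pos": pos0 + 1,
        "ref": refs,
        "alt": alts,
    })
    return HaplotypePanel(population, variants, cols)


def simulate_two_population_panels(
    spec: GenomeSpec,
    shared_variants: int = 200,
    ld_divergence: float = 0.5,
    seed: int = 0,
    n_samples: int = 500,
    n_pairs: int = 20,
    pair_r2: float = 0.9,
    maf_range: tuple[float, float] = (0.1, 0.5),
    populations: tuple[str, str] = ("AFR", "EUR"),
    pair_spacing: int = 10_000,
) -> tuple[HaplotypePanel, HaplotypePanel, TruthTable]:
    """Two panels over one shared variant list, with planted proxy pairs.

    ``n_pairs`` (index, proxy) pairs are planted; a fraction
    ``ld_divergence`` of them reach r^2 ~ ``pair_r2`` only in the first
    population (the proxy is independent in the second), the rest in both.
    Remaining variants are unlinked background.  The TruthTable records
    every pair with its per-population r^2 target and dual flag.
    """
    if not 0.0 <= ld_divergence <= 1.0:
        raise ValueError("ld_divergence must lie in [0, 1]")
    _maf_check(maf_range)
    if 2 * n_pairs > shared_variants:
        raise ValueError("not enough variants for the requested pairs")
    rng = np.random.default_rng(seed)
    chrom = spec.chromosomes[0]
    length = spec.length_by_chrom[chrom]
    n_hap = 2 * n_samples
    n_single = int(round(ld_divergence * n_pairs))

    # layout: pair k occupies positions anchor_k and anchor_k + pair_spacing
    anchors = np.linspace(length * 0.05, length * 0.9, n_pairs).astype(int)
    pair_pos = []
    for a in anchors:
        pair_pos += [int(a), int(a) + pair_spacing]
    n_background = shared_variants - 2 * n_pairs
    taken = set(pair_pos)
    bg_pos = []
    while len(bg_pos) < n_background:
        p = int(rng.integers(0, length))
        if p not in taken:
            taken.add(p)
            bg_pos.append(p)
    all_pos = pair_pos + sorted(bg_pos)

    ids = []
    for k in range(n_pairs):
        ids += [f"idx{k}", f"prox{k}"]
    ids += [f"bg{j}" for j in range(n_background)]

    m_pair = 1.0 - np.sqrt(pair_r2)
    columns = {pop: np.empty((n_hap, shared_variants), dtype=np.int8)
               for pop in populations}
    rngs = {pop: np.random.default_rng(rng.integers(0, 2**31 - 1))
            for pop in populations}
    records = []
    for k in range(n_pairs):
        dual = k >= n_single
        for pop_i, pop in enumerate(populations):
            r = rngs[pop]
            p = r.uniform(*maf_range)
            template = (r.random(n_hap) < p).astype(np.int8)
            while not 0 < template.sum() < n_hap:
                template = (r.random(n_hap) < p).astype(np.int8)
            columns[pop][:, 2 * k] = template
            high_here = dual or pop_i == 0
            if high_here:
                columns[pop][:, 2 * k + 1] = _polymorphic_copy(r, template, p, m_pair)
            else:
                q = r.uniform(*maf_range)
                col = (r.random(n_hap) < q).astype(np.int8)
                while not 0 < col.sum() < n_hap:
                    col = (r.random(n_hap) < q).astype(np.int8)
                columns[pop][:, 2 * k + 1] = col
            records.append({"index_id": f"idx{k}", "proxy_id": f"prox{k}",
                            "population": pop,
                            "r2_target": pair_r2 if high_here else 0.0,
                            "dual": dual})
    for j in range(n_background):
        for pop in populations:
            r = rngs[pop]
            p = r.uniform(*maf_range)
            col = (r.random(n_hap) < p).astype(np.int8)
            while not 0 < col.sum() < n_hap:
                col = (r.random(n_hap) < p).astype(np.int8)
            columns[pop][:, 2 * n_pairs + j] = col

    refs, alts = _draw_alleles(rng, shared_variants)
    variants = pd.DataFrame({"id": ids, "chrom": chrom,
                             "pos": np.asarray(all_pos) + 1,
                             "ref": refs, "alt": alts})
    order = np.argsort(variants["pos"].to_numpy(), kind="mergesort")
    variants = variants.iloc[order].reset_index(drop=True)
    panels = tuple(
        HaplotypePanel(pop, variants.copy(), columns[pop][:, order])
        for pop in populations
    )
    truth = TruthTable(proxy_pairs=pd.DataFrame(records))
    truth.validate_ids(list(panels))
    return panels[0], panels[1], truth


def generate_biofeature_tracks(
    spec: GenomeSpec,
    names: list[str],
    density: float = 10.0,
    width_range: tuple[int, int] = (200, 2000),
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Random interval tracks at ``density`` features per Mb.

    Interval counts per chromosome are Poisson; starts are uniform and
    widths uniform in ``width_range``, clipped to chromosome bounds.
    Density zero yields empty tracks; negative density is rejected.
    """
    if density < 0:
        raise ValueError("density must be non-negative")
    lo_w, hi_w = width_range
    if lo_w < 1 or hi_w < lo_w:
        raise ValueError("bad width_range")
    rng = np.random.default_rng(seed)
    out = {}
    for name in names:
        rows = []
        for chrom, length in zip(spec.chromosomes, spec.lengths):
            n = rng.poisson(density * length / 1e6)
            starts = np.sort(rng.integers(0, max(length - hi_w, 1), size=n))
            widths = rng.integers(lo_w, hi_w + 1, size=n)
            for s, w in zip(starts, widths):
                rows.append((chrom, int(s), int(min(s + w, length)), name))
        out[name] = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
    return out


def track_covering(
    name: str,
    variants: pd.DataFrame,
    ids: list[str],
    width: int = 500,
    genome: GenomeSpec | None = None,
) -> pd.DataFrame:
    """A track whose intervals are centered on the given variant ids.

    Handy for planting known biofeature memberships: the listed SNPs are
    guaranteed members, everything far away is not.
    """
    sub = variants[variants["id"].isin(ids)]
    missing = set(ids) - set(sub["id"])
    if missing:
        raise KeyError(f"unknown variant ids: {sorted(missing)[:5]}")
    rows = []
    for r in sub.itertuples():
        p0 = int(r.pos) - 1
        lo = max(p0 - width // 2, 0)
        hi = p0 + width // 2 + 1
        if genome is not None:
            hi = min(hi, genome.length_by_chrom[str(r.chrom)])
        rows.append((r.chrom, lo, hi, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def generate_pwm_library(
    n_pwms: int = 87,
    length_range: tuple[int, int] = (8, 16),
    ic_profile: str = "mixed",
    seed: int = 0,
    pseudocount: float = 1e-3,
) -> list[PWM]:
    """Random PWM library in the spirit of a Factorbook/Homer compilation.

    ``ic_profile`` controls column sharpness: 'high' draws near-consensus
    columns (Dirichlet alpha 0.2), 'low' flat ones (alpha 5), 'mixed'
    alternates per matrix.  Columns sum to 1 exactly (normalised).
    """
    lo, hi = length_range
    if lo < 4:
        raise ValueError("motif length must be >= 4")
    if ic_profile not in ("low", "high", "mixed"):
        raise ValueError("ic_profile must be low|high|mixed")
    rng = np.random.default_rng(seed)
    pwms = []
    for k in range(n_pwms):
        L = int(rng.integers(lo, hi + 1))
        profile = ic_profile if ic_profile != "mixed" else ("high" if k % 2 == 0
                                                            else "low")
        alpha = 0.2 if profile == "high" else 5.0
        mat = rng.dirichlet(np.full(4, alpha), size=L)
        mat /= mat.sum(axis=1, keepdims=True)
        pwms.append(PWM(f"PWM{k:03d}", mat, pseudocount=pseudocount))
    return pwms


def plant_disruptions(
    panel: HaplotypePanel,
    pwms: list[PWM],
    n_planted: int,
    seed: int = 0,
    max_low_freq: float = 0.05,
    tau_match: float = 0.8,
    tau_delta: float = 0.2,
) -> tuple[pd.DataFrame, TruthTable]:
    """Plant allele-disrupting motif contexts for a subset of panel variants.

    Each planted variant sits at its PWM's maximal-weight position inside a
    consensus motif; the matching allele completes the consensus (score 1)
    while the disrupting allele has frequency <= ``max_low_freq`` there.
    Returns a context table (variant_id, pwm, context, var_index,
    match_allele, disrupt_allele) and the TruthTable.  Flanks are rejection-
    sampled so the planted call verifies as a disruption at the given
    thresholds.
    """
    if n_planted > panel.n_variants:
        raise ValueError(
            f"cannot plant {n_planted} disruptions in {panel.n_variants} variants")
    rng = np.random.default_rng(seed)

    usable = []
    for pwm in pwms:
        from .pwm import positional_weights

        w = positional_weights(pwm)
        j = int(np.argmax(w))
        col = pwm.matrix[j]
        c = int(np.argmax(col))
        low = [b for b in range(4) if b != c and col[b] <= max_low_freq]
        if low and col[c] >= 0.5:
            usable.append((pwm, j, c, low))
    if not usable:
        raise ValueError("no PWM offers a plantable high/low-frequency allele pair")

    chosen = rng.choice(panel.n_variants, size=n_planted, replace=False)
    contexts, records = [], []
    base_arr = np.array(list(BASES))
    for i, vi in enumerate(chosen):
        pwm, j, c, low = usable[i % len(usable)]
        L = len(pwm)
        consensus = pwm.consensus()
        match_allele = BASES[c]
        disrupt_allele = BASES[int(rng.choice(low))]
        left_pad, right_pad = L - 1 - j, j
        for _ in range(100):
            flank_l = "".join(base_arr[rng.integers(0, 4, left_pad)])
            flank_r = "".join(base_arr[rng.integers(0, 4, right_pad)])
            context = flank_l + consensus + flank_r
            var_index = left_pad + j
            call = score_allele_disruption(
                pwm, context, var_index, match_allele, disrupt_allele,
                tau_match=tau_match, tau_delta=tau_delta)
            if call.is_disruption:
                break
        else:
            raise RuntimeError(f"failed to plant a verifiable disruption for {pwm.name}")
        vid = panel.variants.loc[vi, "id"]
        contexts.append((vid, pwm.name, context, var_index,
                         match_allele, disrupt_allele))
        records.append({"variant_id": vid, "pwm": pwm.name,
                        "match_allele": match_allele,
                        "disrupt_allele": disrupt_allele})
    ctx = pd.DataFrame(contexts, columns=["variant_id", "pwm", "context",
                                          "var_index", "match_allele",
                                          "disrupt_allele"])
    return ctx, TruthTable(disruptions=pd.DataFrame(records))


def write_dataset(
    out_dir: str | Path,
    panels: list[HaplotypePanel] | None = None,
    tracks: dict[str, pd.DataFrame] | None = None,
    pwms: list[PWM] | None = None,
    plates: pd.DataFrame | None = None,
    truth: TruthTable | None = None,
) -> None:
    """Write a full synthetic dataset as plain-text files (VCF per
    population, BED6 per track, JASPAR-like PWMs, plate CSV, truth TSVs)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for panel in panels or []:
        write_vcf(panel, out / f"{panel.population}.vcf")
    for name, frame in (tracks or {}).items():
        write_bed(frame, out / f"{name}.bed")
    if pwms:
        write_pwms(pwms, out / "pwms.txt")
    if plates is not None:
        plates.to_csv(out / "plates.csv", index=False)
    if truth is not None:
        truth.write(out / "truth")
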