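"""Synthetic proteomes with known composition -> structure coupling.

The generator emits chains whose sequences are drawn from a background
frequency vector with low-complexity blocks planted at known coordinates, and
whose per-residue structure states are sampled from dose-response curves tied
to the residue's *local* amino-acid composition (a centred, edge-truncated
window of the analysis width).  Disorder is sampled jointly as one more
category, with a polar-residue increment.  Chain-level annotations are
sampled with planted odds effects parameterised directly as the target
log-odds-ratio, so every pipeline stage has an exact ground truth.

Dose responses are logistic in the local residue count k:

    g(k) = p_start + (p_end - p_start) / (1 + exp(-slope * (k - midpoint)))

At most one dose response is active per residue — the one whose local count
is largest (ties by declaration order) — so category probabilities are always
well defined; with a single configured dose this reduces to the plain
logistic.  Inactive structural categories share the remaining probability in
proportion to their baseline weights.

The generator makes no attempt to mimic real PDB amino-acid usage, fold
grammar or protein families; it reproduces the *statistical* structure the
analyses assume, with recoverable parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .complexity import (
    ComplexityParams,
    call_lcds,
    window_counts,
    window_entropies,
)
from .core import (
    AMINO_ACIDS,
    AA_INDEX,
    COIL,
    N_AA,
    POLAR,
    AnnotatedChain,
    CategoryMap,
)
from .enrichment import annotation_enrichment
from .io import AnnotationMap, ClusterFile

#: Representative raw structure code emitted for each default category.
CATEGORY_CODE = {
    "alpha_helix": "H",
    "beta_sheet": "E",
    "helix_310_pi": "G",
    "bridge": "B",
    "turn_bend": "T",
    "loop_irregular": COIL,
}

STRUCT_CATEGORIES = tuple(CATEGORY_CODE)


@dataclass(frozen=True)
class LogisticDose:
    """Logistic dose-response of a category probability on local count k."""

    p_start: float
    p_end: float
    midpoint: float
    slope: float

    def __post_init__(self) -> None:
        for p in (self.p_start, self.p_end):
            if not 0.0 < p < 1.0:
                raise ValueError("dose probabilities must lie in (0, 1)")

    def __call__(self, k: np.ndarray | float) -> np.ndarray | float:
        k = np.asarray(k, dtype=float)
        return self.p_start + (self.p_end - self.p_start) / (
            1.0 + np.exp(-self.slope * (k - self.midpoint))
        )


@dataclass(frozen=True)
class PlantedBlock:
    """A low-complexity block planted at a uniform position.

    Each block position takes the block amino acid with probability
    ``composition`` and a background draw otherwise; ``rate`` is the
    per-chain insertion probability.
    """

    amino_acid: str
    length: int = 20
    composition: float = 1.0
    rate: float = 0.1

    def __post_init__(self) -> None:
        if self.amino_acid not in AA_INDEX:
            raise ValueError(f"unknown amino acid {self.amino_acid!r}")
        if self.length < 1 or not 0.0 < self.composition <= 1.0:
            raise ValueError("bad block length/composition")
        if not 0.0 <= self.rate <= 1.0:
            raise ValueError("rate must lie in [0, 1]")


@dataclass(frozen=True)
class AnnotationModel:
    """One chain-level annotation with optional planted lnOR effects.

    ``planted`` maps an LCD type (amino acid) to the target log odds ratio of
    the annotation among that type's chains versus the whole proteome (the
    generator solves for the carrier-conditional probability that achieves
    it, given the type's expected carrier fraction).
    """

    annotation_id: str
    name: str = ""
    prevalence: float = 0.2
    planted: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")


@dataclass(frozen=True)
class GeneratorSpec:
    """Full parameterisation of a synthetic proteome."""

    n_chains: int = 500
    length_min: int = 80
    length_max: int = 150
    background: tuple[float, ...] = tuple([1.0 / N_AA] * N_AA)
    blocks: tuple[PlantedBlock, ...] = ()
    dose_response: tuple[tuple[str, str, LogisticDose], ...] = ()
    baseline_structure: tuple[tuple[str, float], ...] = (
        ("alpha_helix", 0.32),
        ("beta_sheet", 0.21),
        ("helix_310_pi", 0.04),
        ("bridge", 0.01),
        ("turn_bend", 0.12),
        ("loop_irregular", 0.30),
    )
    disorder_baseline: float = 0.05
    disorder_polar_bonus: float = 0.05
    annotations: tuple[AnnotationModel, ...] = ()
    local_window: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.length_min < 1:
            raise ValueError("n_chains and lengths must be positive")
        if self.length_max < self.length_min:
            raise ValueError("length_max < length_min")
        bg = np.asarray(self.background)
        if bg.shape != (N_AA,) or np.any(bg < 0) or not math.isclose(
            float(bg.sum()), 1.0, abs_tol=1e-9
        ):
            raise ValueError("background must be a normalised 20-vector")
        base = dict(self.baseline_structure)
        if set(base) != set(STRUCT_CATEGORIES):
            raise ValueError(f"baseline_structure must cover {STRUCT_CATEGORIES}")
        if not math.isclose(sum(base.values()), 1.0, abs_tol=1e-9):
            raise ValueError("baseline structure probabilities must sum to 1")
        seen: set[tuple[str, str]] = set()
        for aa, cat, _ in self.dose_response:
            if aa not in AA_INDEX or cat not in STRUCT_CATEGORIES:
                raise ValueError(f"bad dose target ({aa}, {cat})")
            if (aa, cat) in seen:
                raise ValueError(f"duplicate dose for ({aa}, {cat})")
            seen.add((aa, cat))
        d_max = self.disorder_baseline + self.disorder_polar_bonus
        if not (0.0 <= self.disorder_baseline and d_max < 1.0):
            raise ValueError("disorder probabilities out of range")

    def carrier_fraction(self, lcd_type: str) -> float:
        """Expected fraction of chains carrying >=1 planted block of a type."""
        miss = 1.0
        for blk in self.blocks:
            if blk.amino_acid == lcd_type:
                miss *= 1.0 - blk.rate
        return 1.0 - miss


@dataclass
class GroundTruth:
    """Everything the generator knows: planted coordinates and parameters."""

    blocks: list[dict] = field(default_factory=list)
    planted_lnor: dict[str, float] = field(default_factory=dict)  # "type:ann" -> theta
    carrier_probs: dict[str, float] = field(default_factory=dict)  # "type:ann" -> p1
    dose_response: list[dict] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        return cls(**data)


@dataclass
class SyntheticProteome:
    chains: list[AnnotatedChain]
    clusters: ClusterFile
    annotation_map: AnnotationMap
    truth: GroundTruth
    spec: GeneratorSpec


# ---------------------------------------------------------------------------
# Structure model


def _local_counts(seq_idx: np.ndarray, aa: str, w: int) -> np.ndarray:
    """Count of ``aa`` in each residue's centred, edge-truncated window."""
    n = len(seq_idx)
    ind = (seq_idx == AA_INDEX[aa]).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(ind)])
    i = np.arange(n)
    half = w // 2
    lo = np.clip(i - half, 0, n)
    hi = np.clip(i - half + w, 0, n)
    return cum[hi] - cum[lo]


def residue_category_probs(seq_idx: np.ndarray, spec: GeneratorSpec) -> np.ndarray:
    """Per-residue probabilities over the default categories (disorder last).

    This is the generative law; the recovery report reuses it to form exact
    expectations for any statistic of the emitted annotations.
    """
    n = len(seq_idx)
    base = dict(spec.baseline_structure)
    p0 = np.array([base[c] for c in STRUCT_CATEGORIES])
    probs = np.tile(p0, (n, 1))

    if spec.dose_response:
        ks = np.stack(
            [_local_counts(seq_idx, aa, spec.local_window)
             for aa, _, _ in spec.dose_response]
        )  # (n_doses, n)
        active = np.argmax(ks, axis=0)  # first max wins
        for di, (aa, cat, dose) in enumerate(spec.dose_response):
            sel = active == di
            if not sel.any():
                continue
            ci = STRUCT_CATEGORIES.index(cat)
            g = np.asarray(dose(ks[di, sel]), dtype=float)
            rest = np.delete(np.arange(len(STRUCT_CATEGORIES)), ci)
            scale = (1.0 - g) / (1.0 - p0[ci])
            probs[np.ix_(sel, rest)] = p0[rest] * scale[:, None]
            probs[sel, ci] = g

    polar_idx = np.isin(seq_idx, [AA_INDEX[a] for a in sorted(POLAR)])
    p_dis = spec.disorder_baseline + spec.disorder_polar_bonus * polar_idx
    out = np.empty((n, len(STRUCT_CATEGORIES) + 1))
    out[:, :-1] = probs * (1.0 - p_dis)[:, None]
    out[:, -1] = p_dis
    return out


def _sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(probs.shape[0])
    return (u[:, None] > cum).sum(axis=1)


def _solve_carrier_prob(theta: float, q: float, pi: float) -> float:
    """Carrier annotation probability achieving a target lnOR.

    Solves ``ln(odds(p1) / odds((1-pi) q + pi p1)) = theta`` for ``p1``.
    """
    if theta == 0.0:
        return q

    def f(p1: float) -> float:
        pbar = (1 - pi) * q + pi * p1
        return math.log(p1 / (1 - p1)) - math.log(pbar / (1 - pbar)) - theta

    lo, hi = (q, 1 - 1e-12) if theta > 0 else (1e-12, q)
    return float(brentq(f, lo, hi, xtol=1e-14))


# ---------------------------------------------------------------------------
# Generation


def generate_proteome(
    spec: GeneratorSpec, out_dir: str | Path | None = None
) -> SyntheticProteome:
    """Generate a proteome; optionally write all artefacts to ``out_dir``.

    Identical spec (including seed) produces byte-identical files.  Emits one
    singleton cluster per chain so representative selection is the identity.
    """
    rng = np.random.default_rng(spec.seed)
    bg = np.asarray(spec.background)
    truth = GroundTruth(
        dose_response=[
            {"amino_acid": aa, "category": cat, **asdict(dose)}
            for aa, cat, dose in spec.dose_response
        ]
    )

    lengths = rng.integers(spec.length_min, spec.length_max + 1, size=spec.n_chains)
    chains: list[AnnotatedChain] = []
    carrier_types: list[set[str]] = []
    for i in range(spec.n_chains):
        n = int(lengths[i])
        cid = f"SYN{i:05d}_A"
        seq_idx = rng.choice(N_AA, size=n, p=bg).astype(np.int8)
        types: set[str] = set()
        for blk in spec.blocks:
            if blk.length > n or rng.random() >= blk.rate:
                continue
            start = int(rng.integers(0, n - blk.length + 1))
            hit = rng.random(blk.length) < blk.composition
            fill = rng.choice(N_AA, size=blk.length, p=bg)
            seg = np.where(hit, AA_INDEX[blk.amino_acid], fill).astype(np.int8)
            seq_idx[start : start + blk.length] = seg
            types.add(blk.amino_acid)
            truth.blocks.append(
                {
                    "chain_id": cid,
                    "start": start,
                    "end": start + blk.length,
                    "amino_acid": blk.amino_acid,
                    "composition": blk.composition,
                }
            )
        probs = residue_category_probs(seq_idx, spec)
        cat = _sample_categorical(probs, rng)
        dis_idx = len(STRUCT_CATEGORIES)
        ss = "".join(
            CATEGORY_CODE[STRUCT_CATEGORIES[c]] if c < dis_idx else COIL
            for c in cat
        )
        mask = cat == dis_idx
        seq = "".join(AMINO_ACIDS[j] for j in seq_idx)
        chains.append(AnnotatedChain(cid, seq, ss, mask))
        carrier_types.append(types)

    chain_ann: dict[str, set[str]] = {c.chain_id: set() for c in chains}
    names: dict[str, str] = {}
    for model in spec.annotations:
        names[model.annotation_id] = model.name
        p1: dict[str, float] = {}
        for lcd_type, theta in model.planted:
            pi = spec.carrier_fraction(lcd_type)
            if pi == 0.0:
                raise ValueError(
                    f"annotation {model.annotation_id}: planted effect on type "
                    f"{lcd_type} but no blocks of that type"
                )
            p1[lcd_type] = _solve_carrier_prob(theta, model.prevalence, pi)
            truth.planted_lnor[f"{lcd_type}:{model.annotation_id}"] = theta
            truth.carrier_probs[f"{lcd_type}:{model.annotation_id}"] = p1[lcd_type]
        for chain, types in zip(chains, carrier_types):
            p = max(
                (p1[t] for t in types if t in p1), default=model.prevalence
            )
            if rng.random() < p:
                chain_ann[chain.chain_id].add(model.annotation_id)

    clusters = ClusterFile(tuple((c.chain_id,) for c in chains))
    annmap = AnnotationMap(
        {cid: frozenset(a) for cid, a in chain_ann.items() if a}, names
    )
    proteome = SyntheticProteome(chains, clusters, annmap, truth, spec)
    if out_dir is not None:
        write_proteome(proteome, out_dir)
    return proteome


def write_proteome(proteome: SyntheticProteome, out_dir: str | Path) -> None:
    from . import io as io_formats

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    io_formats.write_annotated_chains(proteome.chains, out / "proteome.fasta")
    io_formats.write_cluster_file(proteome.clusters, out / "clusters.txt")
    io_formats.write_annotation_map(proteome.annotation_map, out / "annotations.tsv")
    proteome.truth.to_json(out / "ground_truth.json")


# ---------------------------------------------------------------------------
# Default study specs


def demo_spec(n_chains: int = 500, seed: int = 0) -> GeneratorSpec:
    """An end-to-end demonstration proteome exercising every stage.

    Blocks for ten amino acids spanning the physicochemical groups at 80%
    composition guarantee populated enriched-LCD pools; three dose responses
    couple composition to helix, sheet and irregular structure; one planted
    annotation effect gives the enrichment stage a known signal.
    """
    blocks = tuple(
        PlantedBlock(aa, length=20, composition=0.8, rate=0.08)
        for aa in "ALVEKSNQGP"
    )
    doses = (
        ("A", "alpha_helix", LogisticDose(0.32, 0.90, 5.0, 0.9)),
        ("V", "beta_sheet", LogisticDose(0.21, 0.80, 5.0, 0.9)),
        ("P", "loop_irregular", LogisticDose(0.30, 0.75, 4.0, 0.8)),
    )
    annotations = (
        AnnotationModel("PF90001", "planted A-coupled fold", 0.2, (("A", 1.39),)),
        AnnotationModel("PF90002", "null fold beta", 0.3),
        AnnotationModel("PF90003", "null fold gamma", 0.15),
        AnnotationModel("PF90004", "null fold delta", 0.25),
    )
    return GeneratorSpec(
        n_chains=n_chains, blocks=blocks, dose_response=doses,
        annotations=annotations, seed=seed,
    )


def dose_recovery_spec(n_chains: int = 2000, seed: int = 0) -> GeneratorSpec:
    """Study conditions for dose-response recovery on the A/helix curve.

    Alanine blocks at three compositions populate the full residue-count
    range so per-bin means are estimable up to k = 12.
    """
    blocks = (
        PlantedBlock("A", length=20, composition=1.0, rate=0.15),
        PlantedBlock("A", length=20, composition=0.75, rate=0.15),
        PlantedBlock("A", length=20, composition=0.5, rate=0.15),
    )
    doses = (("A", "alpha_helix", LogisticDose(0.32, 0.95, 6.0, 1.0)),)
    return GeneratorSpec(
        n_chains=n_chains, blocks=blocks, dose_response=doses, seed=seed
    )


def enrichment_recovery_spec(n_chains: int = 2000, seed: int = 0) -> GeneratorSpec:
    """Study conditions for planted-lnOR recovery.

    Pure alanine blocks (always called, unambiguous) carried by 10% of
    chains, with one annotation planted at lnOR = 1.39 (odds ratio 4) and
    three null annotations.
    """
    blocks = (PlantedBlock("A", length=20, composition=1.0, rate=0.10),)
    annotations = (
        AnnotationModel("PF90001", "planted A-coupled fold", 0.2, (("A", 1.39),)),
        AnnotationModel("PF90002", "null fold beta", 0.3),
        AnnotationModel("PF90003", "null fold gamma", 0.15),
        AnnotationModel("PF90004", "null fold delta", 0.25),
    )
    return GeneratorSpec(
        n_chains=n_chains, blocks=blocks, annotations=annotations, seed=seed
    )


def synthetic_scales(
    n_helix: int = 3, n_sheet: int = 3, seed: int = 0
) -> list["PropensityScale"]:
    """Synthetic stand-ins for published propensity scales (test/demo only).

    Values are independent standard-normal draws per amino acid; one sheet
    scale carries a glycine exclusion and one helix scale a lower-is-more
    orientation, so downstream exclusion and orientation handling is
    exercised.  These are not transcriptions of any published scale.
    """
    from .io import PropensityScale

    rng = np.random.default_rng(seed)
    scales: list[PropensityScale] = []
    for kind, count in (("helix", n_helix), ("sheet", n_sheet)):
        for i in range(count):
            values = tuple(
                (aa, float(np.round(rng.normal(), 3))) for aa in AMINO_ACIDS
            )
            orientation = (
                "lower_is_more" if kind == "helix" and i == count - 1
                else "higher_is_more"
            )
            excluded = frozenset("G") if kind == "sheet" and i == 0 else frozenset()
            scales.append(
                PropensityScale(
                    name=f"synthetic_{kind}_{i+1}",
                    kind=kind,
                    values=values,
                    orientation=orientation,
                    excluded=excluded,
                )
            )
    return scales


# ---------------------------------------------------------------------------
# Recovery reporting


def dose_recovery(
    chains: Sequence[AnnotatedChain],
    spec: GeneratorSpec,
    amino_acid: str,
    category: str,
    w: int = 12,
    z: float = 1.96,
) -> pd.DataFrame:
    """Per-bin recovered vs expected mean category fraction with 95% bands.

    The recovered value is the window-level bin mean the profiling stage
    reports.  Because generation is per-residue (each residue's probability
    depends on its own local window) and overlapping windows reuse residue
    draws, the exact expectation and variance of the bin mean are computed as
    a weighted sum of independent residue Bernoullis, with weights equal to
    each residue's multiplicity across the bin's windows.
    """
    cmap = CategoryMap.default()
    ci = cmap.index_of(category)
    j = AA_INDEX[amino_acid]
    obs = np.zeros(w + 1)
    exp = np.zeros(w + 1)
    var = np.zeros(w + 1)
    n_win = np.zeros(w + 1, dtype=np.int64)
    kernel = np.ones(w)
    for chain in chains:
        counts, valid = window_counts(chain, w)
        if counts.shape[0] == 0:
            continue
        cat = cmap.residue_categories(chain)
        hit = (cat == ci).astype(np.int64)
        cum_hit = np.concatenate([[0], np.cumsum(hit)])
        probs = residue_category_probs(chain.seq_indices, spec)[:, ci]
        ks = counts[:, j]
        starts = np.arange(counts.shape[0])
        for k in np.unique(ks[valid]):
            sel = np.zeros(counts.shape[0])
            sel[starts[valid & (ks == k)]] = 1.0
            m = np.convolve(sel, kernel)[: len(chain)]  # residue multiplicity
            nk = int(sel.sum())
            n_win[k] += nk
            obs[k] += float(
                (cum_hit[starts + w] - cum_hit[starts])[sel.astype(bool)].sum()
            )
            exp[k] += float((m * probs).sum())
            var[k] += float((m**2 * probs * (1 - probs)).sum())
    rows = []
    for k in range(w + 1):
        if n_win[k] == 0:
            continue
        denom = w * n_win[k]
        mean_obs = obs[k] / denom
        mean_exp = exp[k] / denom
        sd = math.sqrt(var[k]) / denom
        rows.append(
            {
                "k": k,
                "n_windows": int(n_win[k]),
                "observed_mean": mean_obs,
                "expected_mean": mean_exp,
                "lower": mean_exp - z * sd,
                "upper": mean_exp + z * sd,
                "covered": bool(mean_exp - z * sd <= mean_obs <= mean_exp + z * sd),
            }
        )
    return pd.DataFrame(rows)


def caller_sensitivity(
    chains: Sequence[AnnotatedChain],
    truth: GroundTruth,
    params: ComplexityParams = ComplexityParams(),
) -> float:
    """Fraction of eligible planted blocks hit by a correct-type LCD call.

    A block is eligible when its realised sequence still contains at least
    one full window at or below the entropy threshold whose argmax set
    includes the block's amino acid (a later block of another type may
    overwrite part of it); blocks planted at 100% composition and left
    intact always are.  A hit is any called segment of the block's type
    overlapping the block.  Returns NaN when no block is eligible.
    """
    by_chain: dict[str, list[dict]] = {}
    for blk in truth.blocks:
        by_chain.setdefault(blk["chain_id"], []).append(blk)
    eligible = hit = 0
    for chain in chains:
        blocks = by_chain.get(chain.chain_id)
        if not blocks:
            continue
        segments = call_lcds(chain, params)
        for blk in blocks:
            sub = chain.subchain(blk["start"], blk["end"])
            counts, valid = window_counts(sub, params.window_length)
            if counts.shape[0] == 0:
                continue
            ent = window_entropies(counts, params.window_length)
            is_type_max = (
                counts[:, AA_INDEX[blk["amino_acid"]]]
                == counts.max(axis=1)
            )
            if not np.any(valid & is_type_max & (ent <= params.entropy_threshold)):
                continue
            eligible += 1
            if any(
                blk["amino_acid"] in s.types
                and s.start < blk["end"]
                and s.end > blk["start"]
                for s in segments
            ):
                hit += 1
    return hit / eligible if eligible else float("nan")


def lnor_recovery(
    chains: Sequence[AnnotatedChain],
    annotation_map: AnnotationMap,
    truth: GroundTruth,
    params: ComplexityParams = ComplexityParams(),
) -> pd.DataFrame:
    """Recovered vs planted lnOR for every planted (type, annotation) effect."""
    by_type: dict[str, set[str]] = {}
    for chain in chains:
        for seg in call_lcds(chain, params):
            for aa in seg.types:
                by_type.setdefault(aa, set()).add(chain.chain_id)
    targets = [key.split(":", 1) for key in sorted(truth.planted_lnor)]
    wanted_types = {t for t, _ in targets}
    records = annotation_enrichment(
        {t: by_type.get(t, set()) for t in wanted_types if by_type.get(t)},
        annotation_map,
        [c.chain_id for c in chains],
    )
    rows = []
    for lcd_type, ann in targets:
        sub = records[
            (records["lcd_type"] == lcd_type) & (records["annotation_id"] == ann)
        ]
        recovered = float(sub["lnor"].iloc[0]) if len(sub) else float("nan")
        planted = truth.planted_lnor[f"{lcd_type}:{ann}"]
        rows.append(
            {
                "lcd_type": lcd_type,
                "annotation_id": ann,
                "planted_lnor": planted,
                "recovered_lnor": recovered,
                "abs_error": abs(recovered - planted),
            }
        )
    return pd.DataFrame(rows)


def recovery_report(
    proteome: SyntheticProteome,
    params: ComplexityParams = ComplexityParams(),
) -> dict[str, object]:
    """Bundle dose, enrichment and caller recovery for one proteome.

    A missing ingredient (no dose responses, no planted annotations, no
    blocks) yields an explicit ``None`` gap for that entry, not a failure.
    """
    out: dict[str, object] = {"dose": None, "lnor": None, "sensitivity": None}
    spec, truth = proteome.spec, proteome.truth
    if spec.dose_response:
        aa, cat, _ = spec.dose_response[0]
        out["dose"] = dose_recovery(proteome.chains, spec, aa, cat, spec.local_window)
    if truth.planted_lnor and proteome.annotation_map.chain_annotations:
        out["lnor"] = lnor_recovery(
            proteome.chains, proteome.annotation_map, truth, params
        )
    if truth.blocks:
        out["sensitivity"] = caller_sensitivity(proteome.chains, truth, params)
    return out


# ---------------------------------------------------------------------------
# Scaled-down null study for the enrichment type-I rate


def null_typeI_rate(
    n_proteomes: int = 200,
    n_chains: int = 6000,
    carrier_rate: float = 0.03,
    prevalences: Sequence[float] = (0.3, 0.35, 0.4, 0.45, 0.5),
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[float, int]:
    """Raw-p rejection rate when annotations are independent of LCD type.

    Operates at the chain-label level: LCD-type membership and annotations
    are drawn independently per chain, and the enrichment test is applied to
    each (type, annotation) pair — sequence content is irrelevant to the
    statistic under this null.  Returns ``(rate, n_pairs)``.

    The defaults keep the study in the near-continuous regime of the exact
    test: large tables blunt the discreteness of the Fisher p distribution,
    and a small LCD-set fraction keeps the deflation from comparing a subset
    against the full reference (which includes it) mild.  With heavily
    discrete tables or a large subset fraction the exact test is markedly
    conservative and the empirical rate falls well below the nominal level.
    """
    rng = np.random.default_rng(seed)
    rejected = total = 0
    for _ in range(n_proteomes):
        ids = [f"C{i:05d}" for i in range(n_chains)]
        carriers = {
            cid for cid in ids if rng.random() < carrier_rate
        }
        chain_ann: dict[str, set[str]] = {cid: set() for cid in ids}
        for j, q in enumerate(prevalences):
            ann = f"ANN{j}"
            draws = rng.random(n_chains) < q
            for cid, hit in zip(ids, draws):
                if hit:
                    chain_ann[cid].add(ann)
        annmap = AnnotationMap(
            {cid: frozenset(a) for cid, a in chain_ann.items() if a}
        )
        records = annotation_enrichment({"A": carriers}, annmap, ids)
        rejected += int((records["p_raw"] <= alpha).sum())
        total += len(records)
    return rejected / total, total
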