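"""Synthetic inputs with planted, recoverable structure.

Every generator is a pure function of its parameters and seed.  The
planted truth (labels, motif instances, generator parameters) is carried
in a :class:`SyntheticTruth` that suffices to score every recovery
metric downstream.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .atlas import LifeStageLabel
from .celltype import CellTypeLabel
from .conservation import ConservationGroup
from .enrichment import ValidationRegion
from .pwm import PWM
from .tracks import ElementSet, GenomicInterval, SignalTrack

__all__ = [
    "SyntheticTruth",
    "generate_genome_and_elements",
    "simulate_accessibility_tracks",
    "simulate_alignment_fractions",
    "simulate_importance_tracks",
    "simulate_expression_and_regions",
]

BASES = np.array(list("ACGT"))

# default planted label proportions
LIFE_STAGE_PROBS = {
    LifeStageLabel.ADULT_SPECIFIC: 0.05,
    LifeStageLabel.FETAL_SPECIFIC: 0.05,
    LifeStageLabel.ADULT_FETAL_SHARED: 0.05,
    LifeStageLabel.NON_BRAIN: 0.85,
}
CELL_TYPE_PROBS = {
    CellTypeLabel.NEURON_SPECIFIC: 0.3,
    CellTypeLabel.GLIA_SPECIFIC: 0.3,
    CellTypeLabel.NEURON_GLIA_SHARED: 0.3,
    CellTypeLabel.LOW_SIGNAL: 0.1,
}
GROUP_PROBS = {
    ConservationGroup.G1: 0.25,
    ConservationGroup.G2: 0.25,
    ConservationGroup.G3: 0.25,
    ConservationGroup.OTHER: 0.25,
}

CLADES_NEAR_TO_FAR = (
    "great-ape",
    "old-world-monkey",
    "new-world-monkey",
    "lemur",
    "non-primate-mammal",
)


@dataclass
class SyntheticTruth:
    """Planted per-element labels, motif instances and generator parameters."""

    life_stage: dict[str, str] = field(default_factory=dict)
    cell_type: dict[str, str] = field(default_factory=dict)
    conservation_group: dict[str, str] = field(default_factory=dict)
    origin_clade: dict[str, str] = field(default_factory=dict)
    #: (element id, offset within element, motif id, strand, cell type)
    motif_instances: list[tuple[str, int, str, str, str]] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["motif_instances"] = [tuple(t) for t in d.get("motif_instances", [])]
        return cls(**d)

    def ids_with_life_stage(self, *labels: str) -> set[str]:
        want = set(labels)
        return {i for i, l in self.life_stage.items() if l in want}

    def ids_with_cell_type(self, *labels: str) -> set[str]:
        want = set(labels)
        return {i for i, l in self.cell_type.items() if l in want}


def generate_genome_and_elements(
    seed: int,
    n_chroms: int = 3,
    chrom_len: int = 1_000_000,
    n_elements: int = 5000,
    element_len: int = 300,
    min_gap: int = 100,
    gc: float = 0.5,
) -> tuple[dict[str, str], ElementSet, SyntheticTruth]:
    """Random genome, non-overlapping elements, and planted labels.

    Nucleotides are i.i.d. with the requested GC fraction; elements are
    placed on a slot grid guaranteeing >= ``min_gap`` bp between
    neighbors.  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    slot = element_len + min_gap
    slots_per_chrom = chrom_len // slot
    total_slots = slots_per_chrom * n_chroms
    if n_elements > total_slots:
        raise ValueError(
            f"cannot place {n_elements} elements of {element_len} bp with "
            f"{min_gap} bp gaps in {n_chroms} x {chrom_len} bp"
        )
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {
        f"chr{i + 1}": "".join(rng.choice(BASES, size=chrom_len, p=p))
        for i in range(n_chroms)
    }
    chosen = np.sort(rng.choice(total_slots, size=n_elements, replace=False))
    elems = []
    for k, slot_idx in enumerate(chosen):
        ci, si = divmod(int(slot_idx), slots_per_chrom)
        start = si * slot + min_gap // 2
        elems.append(
            GenomicInterval(f"chr{ci + 1}", start, start + element_len, f"E{k:05d}")
        )
    elements = ElementSet(elems)

    truth = SyntheticTruth(
        params={
            "seed": seed,
            "n_chroms": n_chroms,
            "chrom_len": chrom_len,
            "n_elements": n_elements,
            "element_len": element_len,
            "min_gap": min_gap,
            "gc": gc,
        }
    )
    ls_labels = list(LIFE_STAGE_PROBS)
    ls_p = np.array(list(LIFE_STAGE_PROBS.values()))
    ct_labels = list(CELL_TYPE_PROBS)
    ct_p = np.array(list(CELL_TYPE_PROBS.values()))
    gp_labels = list(GROUP_PROBS)
    gp_p = np.array(list(GROUP_PROBS.values()))
    for e in elements:
        ls = ls_labels[int(rng.choice(len(ls_labels), p=ls_p))]
        truth.life_stage[e.id] = ls.value
        if ls is not LifeStageLabel.NON_BRAIN:
            ct = ct_labels[int(rng.choice(len(ct_labels), p=ct_p))]
            truth.cell_type[e.id] = ct.value
        truth.conservation_group[e.id] = gp_labels[
            int(rng.choice(len(gp_labels), p=gp_p))
        ].value
    return genome, elements, truth


def _experiment_active(life_stage: str, cell_type: str | None, exp_class: str) -> bool:
    brain_adult = life_stage in ("adult-specific", "adult-fetal-shared")
    brain_fetal = life_stage in ("fetal-specific", "adult-fetal-shared")
    if exp_class == "adult":
        return brain_adult
    if exp_class == "fetal":
        return brain_fetal
    if exp_class == "neuron":
        return cell_type in ("neuron-specific", "neuron-glia-shared")
    if exp_class == "glia":
        return cell_type in ("glia-specific", "neuron-glia-shared")
    raise ValueError(f"unknown experiment class: {exp_class}")


def simulate_accessibility_tracks(
    elements: ElementSet,
    truth: SyntheticTruth,
    n_adult: int = 20,
    n_fetal: int = 6,
    n_neuron: int = 4,
    n_glia: int = 4,
    signal_shift_sd: float = 2.5,
    celltype_shift_sd: float = 4.0,
    noise_sd: float = 1.0,
    baseline: float = 1.0,
    seed: int = 0,
) -> tuple[dict[str, SignalTrack], dict[str, str]]:
    """Per-experiment accessibility tracks with planted class structure.

    Per element and experiment, log-signal = baseline + shift x 1[element
    planted active in the experiment's class] + Normal(0, noise_sd); the
    exponentiated value covers the element extent, background elsewhere
    is 0.  Returns (tracks by experiment id, experiment id -> class).
    """
    rng = np.random.default_rng(seed)
    exp_classes: dict[str, str] = {}
    for cls, n in (
        ("adult", n_adult),
        ("fetal", n_fetal),
        ("neuron", n_neuron),
        ("glia", n_glia),
    ):
        for i in range(n):
            exp_classes[f"{cls}_{i:02d}"] = cls
    tracks: dict[str, SignalTrack] = {}
    by_chrom = elements.by_chrom()
    for exp_id, cls in exp_classes.items():
        runs: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, (starts, ends, ids) in by_chrom.items():
            noise = rng.normal(0.0, noise_sd, size=len(ids))
            vals = []
            shift = celltype_shift_sd if cls in ("neuron", "glia") else signal_shift_sd
            for eid, eps in zip(ids, noise):
                active = _experiment_active(
                    truth.life_stage[eid], truth.cell_type.get(eid), cls
                )
                logsig = baseline + (shift if active else 0.0) + eps
                vals.append(float(np.exp(logsig)))
            runs[chrom] = [
                (int(s), int(e), v) for s, e, v in zip(starts, ends, vals)
            ]
        tracks[exp_id] = SignalTrack.from_runs(runs)
    return tracks, exp_classes


def simulate_alignment_fractions(
    elements: ElementSet,
    truth: SyntheticTruth,
    n_species: int = 40,
    n_primates: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Elements x species alignment fractions with planted G1/G2/G3 groups.

    G1: fractions >= 0.9 in a majority of species.  G2: >= 0.9 in some
    and <= 0.1 in others (each at least 10% of species, without reaching
    a G1 majority).  G3: <= 0.1 in most non-primates with a handful of
    highly aligning primates (too few for the G2 minimum).  Other:
    intermediate fractions everywhere.  Also returns species metadata
    (species, clade, distance rank) consistent with the planted origin
    clades being recoverable.
    """
    rng = np.random.default_rng(seed)
    species = [f"sp{i:02d}" for i in range(n_species)]
    n_np = n_species - n_primates
    primate_clades = [c for c in CLADES_NEAR_TO_FAR if c != "non-primate-mammal"]
    clades = [primate_clades[i % len(primate_clades)] for i in range(n_primates)]
    clades += ["non-primate-mammal"] * n_np
    meta = pd.DataFrame(
        {"species": species, "clade": clades, "distance_rank": np.arange(n_species)}
    ).set_index("species")

    g2_min = int(np.ceil(0.1 * n_species))
    g1_min = int(np.floor(0.5 * n_species)) + 1
    rows = np.empty((len(elements), n_species))
    mid = lambda size: rng.uniform(0.25, 0.75, size=size)  # noqa: E731
    hi = lambda size: rng.uniform(0.92, 1.0, size=size)  # noqa: E731
    lo = lambda size: rng.uniform(0.0, 0.08, size=size)  # noqa: E731
    for i, e in enumerate(elements):
        group = truth.conservation_group[e.id]
        f = mid(n_species)
        if group == "G1":
            k1 = int(rng.integers(g1_min, n_species + 1))
            idx = rng.choice(n_species, size=k1, replace=False)
            f[idx] = hi(k1)
        elif group == "G2":
            k1 = int(rng.integers(g2_min, g1_min - 1))
            k2 = int(rng.integers(g2_min, n_species - k1 + 1))
            idx = rng.permutation(n_species)
            f[idx[:k1]] = hi(k1)
            f[idx[k1 : k1 + k2]] = lo(k2)
        elif group == "G3":
            # a few conserved primates, below the G2 minimum
            k1 = int(rng.integers(1, min(g2_min, n_primates)))
            pidx = rng.choice(n_primates, size=k1, replace=False)
            f[:n_primates] = mid(n_primates)
            f[pidx] = hi(k1)
            f[n_primates:] = lo(n_np)
        rows[i] = f
    frac = pd.DataFrame(rows, index=elements.ids, columns=species)
    # record the origin clade implied by the generated fractions as truth
    from .conservation import evolutionary_origin

    for eid, f in zip(elements.ids, rows):
        truth.origin_clade[eid] = evolutionary_origin(
            f, clades, CLADES_NEAR_TO_FAR, min_align_frac=0.5
        )
    return frac, meta


def simulate_importance_tracks(
    elements: ElementSet,
    truth: SyntheticTruth,
    catalog: Mapping[str, PWM],
    cell_types: Sequence[str] = ("neuron", "glia"),
    site_z: float = 3.0,
    neg_site_frac: float = 0.25,
    sites_per_element: int = 2,
    seed: int = 0,
) -> tuple[dict[str, SignalTrack], SyntheticTruth]:
    """Base-resolution importance tracks with planted motif instances.

    Background scores are Normal(0, 1) over each element window; planted
    sites (motif-consensus length) get mean ``site_z``, with a fraction
    planted as negative (-``site_z``).  Sites are planted only in
    elements whose planted cell-type label matches the track's cell type.
    Returns (per-cell-type tracks, truth updated with planted sites).
    """
    rng = np.random.default_rng(seed)
    motif_ids = sorted(catalog)
    tracks: dict[str, SignalTrack] = {}
    for ct in cell_types:
        match = {
            f"{ct}-specific",
            "neuron-glia-shared" if ct in ("neuron", "glia") else f"{ct}-shared",
        }
        runs: dict[str, list[tuple[int, int, float]]] = {}
        for e in elements:
            scores = rng.normal(0.0, 1.0, size=len(e))
            if truth.cell_type.get(e.id) in match:
                used: list[tuple[int, int]] = []
                for _ in range(sites_per_element):
                    mid_ = motif_ids[int(rng.integers(len(motif_ids)))]
                    L = len(catalog[mid_])
                    for _attempt in range(20):
                        off = int(rng.integers(0, len(e) - L))
                        if all(off + L + 3 <= s or off >= t + 3 for s, t in used):
                            break
                    else:
                        continue
                    used.append((off, off + L))
                    sign = -1.0 if rng.random() < neg_site_frac else 1.0
                    scores[off : off + L] = rng.normal(sign * site_z, 0.5, size=L)
                    strand = "+" if sign > 0 else "-"
                    truth.motif_instances.append((e.id, off, mid_, strand, ct))
            runs.setdefault(e.chrom, []).extend(
                (e.start + i, e.start + i + 1, float(scores[i]))
                for i in range(len(e))
            )
        # compact adjacent single-base runs with equal values is pointless
        # here; keep per-base runs (bedGraph-compatible, exact)
        tracks[ct] = SignalTrack.from_runs(runs, allow_negative=True)
    truth.params.setdefault("importance", {}).update(
        {"site_z": site_z, "neg_site_frac": neg_site_frac, "seed": seed}
    )
    return tracks, truth


def _random_pwm(rng: np.random.Generator, length: int, sharp: float = 0.88) -> PWM:
    consensus = rng.integers(0, 4, size=length)
    m = np.full((length, 4), (1 - sharp) / 3)
    m[np.arange(length), consensus] = sharp
    return PWM(m)


def make_motif_catalog(
    seed: int, n_motifs: int = 20, min_len: int = 8, max_len: int = 12
) -> dict[str, PWM]:
    """Catalog of distinct-consensus synthetic PWMs."""
    rng = np.random.default_rng(seed)
    catalog: dict[str, PWM] = {}
    seen: set[str] = set()
    i = 0
    while len(catalog) < n_motifs:
        pwm = _random_pwm(rng, int(rng.integers(min_len, max_len + 1)))
        if pwm.consensus in seen:
            continue
        seen.add(pwm.consensus)
        catalog[f"M{i:03d}"] = pwm
        i += 1
    return catalog


def simulate_expression_and_regions(
    elements: ElementSet,
    truth: SyntheticTruth,
    seed: int = 0,
    n_motifs: int = 20,
    n_regions: int = 60,
    n_traits: int = 12,
) -> dict:
    """Motif catalog, TF expression, validation regions and an rg matrix.

    TFs whose motifs are planted in a cell type get elevated expression
    statistics there.  Validation regions include the two canonical
    fractional-weighting configurations (one fully contained
    adult-specific plus one fully contained fetal-specific element; one
    fully contained adult-specific element plus half of a non-brain
    element) along with randomly composed regions.  The rg matrix has
    planted correlated trait blocks.
    """
    rng = np.random.default_rng(seed)
    catalog = make_motif_catalog(seed, n_motifs=n_motifs)
    motif_ids = sorted(catalog)
    motif_to_tf = {m: f"TF_{m}" for m in motif_ids}

    planted_by_ct: dict[str, set[str]] = {}
    for _, _, mid_, _, ct in truth.motif_instances:
        planted_by_ct.setdefault(ct, set()).add(mid_)
    expr_rows = []
    for ct in sorted(planted_by_ct) or ["neuron", "glia"]:
        for m in motif_ids:
            stat = rng.normal(0.0, 0.5)
            if m in planted_by_ct.get(ct, set()):
                stat += 3.0
            expr_rows.append(
                {"cell_type": ct, "tf": motif_to_tf[m], "statistic": float(stat)}
            )
    tf_expression = pd.DataFrame(expr_rows)

    # validation regions with known composition
    adult = sorted(truth.ids_with_life_stage("adult-specific"))
    fetal = sorted(truth.ids_with_life_stage("fetal-specific"))
    nonbrain = sorted(truth.ids_with_life_stage("non-brain"))
    regions: list[ValidationRegion] = []

    def _span(eids: list[str], half_last: bool) -> GenomicInterval | None:
        """Smallest region covering the elements, half-covering the last.

        Returns None when any other element would intrude on the span.
        """
        ivs = [elements[i] for i in eids]
        if len({iv.chrom for iv in ivs}) != 1:
            return None
        start = min(iv.start for iv in ivs) - 10
        last = max(ivs, key=lambda iv: iv.start)
        end = (last.start + len(last) // 2) if half_last else max(iv.end for iv in ivs) + 10
        intruders = [
            e
            for e in elements
            if e.chrom == ivs[0].chrom
            and e.start < end
            and e.end > start
            and e.id not in eids
        ]
        if intruders:
            return None
        return GenomicInterval(ivs[0].chrom, max(0, start), end, f"VR{len(regions):03d}")

    # canonical configuration 1: adult + fetal fully contained, adjacent pair
    for a in adult:
        ia = elements[a]
        mates = [
            f
            for f in fetal
            if elements[f].chrom == ia.chrom and 0 < elements[f].start - ia.end < 2000
        ]
        if mates:
            iv = _span([a, mates[0]], half_last=False)
            if iv is not None:
                regions.append(ValidationRegion(iv, frozenset({"forebrain"})))
                break
    # canonical configuration 2: adult fully contained + half a non-brain element
    for a in adult:
        ia = elements[a]
        mates = [
            n
            for n in nonbrain
            if elements[n].chrom == ia.chrom and 0 < elements[n].start - ia.end < 2000
        ]
        if mates:
            iv = _span([a, mates[0]], half_last=True)
            if iv is not None:
                regions.append(ValidationRegion(iv, frozenset({"hindbrain"})))
                break

    tissue_pools = (
        ["forebrain", "midbrain", "hindbrain"],
        ["eye", "neural tube", "cranial nerve"],
        ["limb", "heart", "somite"],
        [],
    )
    candidates = elements.ids
    for _ in range(n_regions):
        eid = candidates[int(rng.integers(len(candidates)))]
        iv0 = elements[eid]
        pad_l = int(rng.integers(0, 400))
        pad_r = int(rng.integers(0, 400))
        iv = GenomicInterval(
            iv0.chrom,
            max(0, iv0.start - pad_l),
            iv0.end + pad_r,
            f"VR{len(regions):03d}",
        )
        ls = truth.life_stage[eid]
        if ls in ("adult-specific", "fetal-specific", "adult-fetal-shared"):
            pool_w = [0.5, 0.2, 0.15, 0.15]
        else:
            pool_w = [0.08, 0.12, 0.4, 0.4]
        pool = tissue_pools[int(rng.choice(4, p=pool_w))]
        n_t = int(rng.integers(1, 3)) if pool else 0
        tissues = frozenset(
            str(t) for t in rng.choice(pool, size=min(n_t, len(pool)), replace=False)
        ) if pool else frozenset()
        regions.append(ValidationRegion(iv, tissues))

    # rg matrix with planted correlated blocks of 3 traits
    traits = [f"trait_{i:02d}" for i in range(n_traits)]
    rg = np.eye(n_traits)
    for b0 in range(0, n_traits - 2, 4):
        block = [b0, b0 + 1, b0 + 2]
        for i in block:
            for j in block:
                if i != j:
                    rg[i, j] = 0.9
    noise = rng.normal(0, 0.02, size=(n_traits, n_traits))
    noise = (noise + noise.T) / 2
    off = ~np.eye(n_traits, dtype=bool)
    rg[off] = np.clip(rg[off] + noise[off], -1, 1)
    rg_df = pd.DataFrame(rg, index=traits, columns=traits)

    return {
        "catalog": catalog,
        "motif_to_tf": motif_to_tf,
        "tf_expression": tf_expression,
        "validation_regions": regions,
        "rg": rg_df,
    }
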