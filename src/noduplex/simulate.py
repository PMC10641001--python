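"""Synthetic study generator.

Emulates the raw material of a rhizobial-inoculant competition study on
Bambara groundnut so that every downstream stage (fingerprint typing,
change-factor competitiveness, ITS phylogeny, RCBD agronomic ANOVA) can be
exercised and validated without any external data:

* a library of tagged reference strains in two phylogenetic clades, a
  deep-branching "novel indigenous" cluster, and a distant outgroup, each
  with ERIC/BOX band profiles and an ITS sequence evolved under a
  Jukes-Cantor process along a fixed known tree;
* multinomial colony/nodule samples for a competition scenario in which the
  realized inoculum mix deviates from equal proportions via a Dirichlet draw;
* balanced randomized-complete-block 3x3 factorial trait tables with
  structural zero nodulation for uninoculated red/cream varieties;
* band observations with gel-measurement jitter, carrying their true strain
  labels in a side column that the typing stage never reads.

All randomness flows from explicit integer seeds; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strains import NUCLEOTIDES, StrainLibrary, StrainProfile

__all__ = [
    "CompetitionScenario",
    "TraitEffects",
    "gen_strain_library",
    "gen_competition_samples",
    "gen_trait_table",
    "gen_fingerprint_observations",
    "default_weights",
    "default_trait_effects",
    "DEFAULT_CELL_MEANS",
    "DEFAULT_CV_PERCENT",
    "VARIETIES",
    "TREATMENTS",
    "TRAITS",
]

VARIETIES = ("red", "brown", "cream")
TREATMENTS = ("0K", "9-5K", "MK")
TRAITS = ("DTE", "PHT30", "PHT60", "DTF", "nodules", "SFW", "SDW")

#: Default strain identifiers for up to seven reference strains (tags A-G);
#: underscores keep the labels FASTA/Newick-safe.
_REFERENCE_IDS = ("1-7", "3B_4-1", "9-5", "36_1-1", "36_3-2", "55_1-1", "60_2-1")

# ---------------------------------------------------------------------------
# default study conditions
# ---------------------------------------------------------------------------

#: Greenhouse-trial cell means (variety x treatment) for the seven agronomic
#: traits of the default scenario: days to emergence, plant height at 30/60
#: days after planting (cm), days to flowering, nodules per plant, shoot
#: fresh/dry weight (g).
DEFAULT_CELL_MEANS = pd.DataFrame(
    {
        "DTE": [11.30, 9.00, 10.70, 10.00, 8.70, 10.00, 14.00, 11.70, 12.00],
        "PHT30": [13.90, 14.50, 14.50, 15.30, 14.10, 17.10, 16.80, 15.80, 17.80],
        "PHT60": [14.60, 14.30, 12.20, 15.60, 14.30, 18.00, 17.70, 17.80, 19.20],
        "DTF": [60.70, 62.00, 59.30, 62.70, 60.00, 58.00, 55.70, 56.30, 56.00],
        "nodules": [3.70, 7.70, 7.70, 0.00, 5.70, 8.70, 0.00, 7.30, 13.00],
        "SFW": [6.00, 6.50, 9.20, 7.70, 6.00, 10.00, 7.30, 7.40, 10.00],
        "SDW": [0.90, 1.00, 1.20, 1.00, 0.90, 1.70, 1.10, 1.10, 1.50],
    },
    index=pd.MultiIndex.from_product(
        [("brown", "cream", "red"), TREATMENTS], names=["variety", "treatment"]
    ),
)

#: Residual coefficients of variation (percent) per trait in the default
#: greenhouse scenario.
DEFAULT_CV_PERCENT = {
    "DTE": 8.5,
    "PHT30": 13.4,
    "PHT60": 14.3,
    "DTF": 2.8,
    "nodules": 72.0,
    "SFW": 2.9,
    "SDW": 1.5,
}

#: Per-variety relative nodulation competitiveness of the seven-strain mix.
#: The red-variety vector is dominated by strain C (0.60) with G and A next;
#: E dominates for brown and cream; B and D are weak or absent competitors.
_DEFAULT_WEIGHTS = {
    "red": {"A": 0.15, "B": 0.0, "C": 0.60, "D": 0.0, "E": 0.05, "F": 0.04, "G": 0.16},
    "brown": {"A": 0.12, "B": 0.20, "C": 0.12, "D": 0.08, "E": 0.25, "F": 0.19, "G": 0.04},
    "cream": {"A": 0.22, "B": 0.03, "C": 0.08, "D": 0.02, "E": 0.43, "F": 0.10, "G": 0.12},
}


def default_weights(variety: str) -> dict[str, float]:
    """Default competitiveness weight vector for one bean variety."""
    try:
        return dict(_DEFAULT_WEIGHTS[variety])
    except KeyError:
        raise ValueError(f"unknown variety {variety!r}; expected one of {VARIETIES}") from None


# ---------------------------------------------------------------------------
# scenario / effects containers
# ---------------------------------------------------------------------------


@dataclass
class CompetitionScenario:
    """Conditions of one phytotron competition assay.

    ``weights`` map reference tags to relative nodulation competitiveness
    (non-negative, summing to 1). ``inoculum_dirichlet_concentration``
    controls how far the realized starter mix wanders from equal
    proportions (larger = closer to equal).
    """

    variety: str
    weights: dict[str, float]
    n_colonies: int = 21
    n_nodules: int = 21
    n_experiments: int = 3
    inoculum_dirichlet_concentration: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variety not in VARIETIES:
            raise ValueError(f"unknown variety {self.variety!r}")
        w = np.asarray(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {w.sum()!r})")
        for n in (self.n_colonies, self.n_nodules, self.n_experiments):
            if n <= 0:
                raise ValueError("counts must be positive")
        if self.inoculum_dirichlet_concentration <= 0:
            raise ValueError("inoculum_dirichlet_concentration must be positive")


@dataclass
class TraitEffects:
    """Linear-model effects generating a balanced factorial trait table.

    Effect vectors sum to zero within each factor, and interaction effects
    sum to zero over each margin, so cell means decompose uniquely.
    ``structural_zero_rules`` lists (variety, treatment) cells whose nodule
    counts are forced to exactly zero (no nodulation without inoculant).
    """

    traits: tuple[str, ...]
    grand_mean: dict[str, float]
    variety_effects: dict[str, dict[str, float]]
    treatment_effects: dict[str, dict[str, float]]
    interaction_effects: dict[str, dict[tuple[str, str], float]]
    block_sd: dict[str, float]
    residual_sd: dict[str, float]
    structural_zero_rules: list[tuple[str, str]] = field(default_factory=list)
    count_traits: tuple[str, ...] = ("nodules",)

    def __post_init__(self) -> None:
        for trait in self.traits:
            for name, eff in (
                ("variety", self.variety_effects[trait]),
                ("treatment", self.treatment_effects[trait]),
            ):
                if abs(sum(eff.values())) > 1e-8:
                    raise ValueError(f"{name} effects for {trait!r} must sum to zero")
            if abs(sum(self.interaction_effects[trait].values())) > 1e-8:
                raise ValueError(f"interaction effects for {trait!r} must sum to zero")
            if self.block_sd[trait] < 0 or self.residual_sd[trait] < 0:
                raise ValueError("standard deviations must be non-negative")

    @classmethod
    def from_cell_means(
        cls,
        cell_means: pd.DataFrame,
        block_sd: dict[str, float] | float = 0.0,
        residual_sd: dict[str, float] | float = 0.0,
        structural_zero_rules: list[tuple[str, str]] | None = None,
        count_traits: tuple[str, ...] = ("nodules",),
    ) -> "TraitEffects":
        """Decompose a (variety, treatment)-indexed cell-mean table into effects."""
        traits = tuple(cell_means.columns)
        if not isinstance(cell_means.index, pd.MultiIndex):
            raise ValueError("cell_means must be indexed by (variety, treatment)")
        if isinstance(block_sd, (int, float)):
            block_sd = {t: float(block_sd) for t in traits}
        if isinstance(residual_sd, (int, float)):
            residual_sd = {t: float(residual_sd) for t in traits}
        grand, v_eff, t_eff, i_eff = {}, {}, {}, {}
        for trait in traits:
            cells = cell_means[trait].unstack("treatment")
            grand[trait] = float(cells.values.mean())
            v = cells.mean(axis=1) - grand[trait]
            t = cells.mean(axis=0) - grand[trait]
            v_eff[trait] = v.to_dict()
            t_eff[trait] = t.to_dict()
            i_eff[trait] = {
                (vi, tj): float(cells.loc[vi, tj] - grand[trait] - v[vi] - t[tj])
                for vi in cells.index
                for tj in cells.columns
            }
        return cls(
            traits=traits,
            grand_mean=grand,
            variety_effects=v_eff,
            treatment_effects=t_eff,
            interaction_effects=i_eff,
            block_sd=block_sd,
            residual_sd=residual_sd,
            structural_zero_rules=list(structural_zero_rules or []),
            count_traits=count_traits,
        )

    def cell_mean(self, trait: str, variety: str, treatment: str) -> float:
        return (
            self.grand_mean[trait]
            + self.variety_effects[trait][variety]
            + self.treatment_effects[trait][treatment]
            + self.interaction_effects[trait][(variety, treatment)]
        )


def default_trait_effects(
    block_sd_fraction: float = 0.5,
    residual_scale: float = 1.0,
) -> TraitEffects:
    """Effects calibrated to the default greenhouse scenario.

    Residual SDs are set from the per-trait CV of that scenario
    (sd = CV/100 x grand mean, scaled by ``residual_scale``); block SDs are
    ``block_sd_fraction`` of the residual SD.
    """
    grand = {t: float(DEFAULT_CELL_MEANS[t].mean()) for t in DEFAULT_CELL_MEANS.columns}
    resid = {
        t: residual_scale * DEFAULT_CV_PERCENT[t] / 100.0 * grand[t]
        for t in DEFAULT_CELL_MEANS.columns
    }
    block = {t: block_sd_fraction * resid[t] for t in resid}
    return TraitEffects.from_cell_means(
        DEFAULT_CELL_MEANS,
        block_sd=block,
        residual_sd=resid,
        structural_zero_rules=[("red", "0K"), ("cream", "0K")],
    )


# ---------------------------------------------------------------------------
# strain library generation
# ---------------------------------------------------------------------------

# Minimum spacing of the synthetic band-size pool; larger than matching
# tolerance + 2x gel jitter at the default settings, so distinct pool bands
# never cross-match.
_BAND_POOL_SPACING = 30
_JC_SATURATION = 0.75


def _jc_evolve(parent: np.ndarray, t: float, rng: np.random.Generator) -> np.ndarray:
    """Evolve an encoded sequence for branch length t (substitutions/site)."""
    if t <= 0:
        return parent.copy()
    p_change = 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
    child = parent.copy()
    hit = rng.random(parent.size) < p_change
    # conditional on change, the new base is uniform over the other three
    child[hit] = (child[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return child


def _decode(seq: np.ndarray) -> str:
    return "".join(NUCLEOTIDES[i] for i in seq)


def _p_distance(a: str, b: str) -> float:
    arr_a = np.frombuffer(a.encode(), dtype=np.uint8)
    arr_b = np.frombuffer(b.encode(), dtype=np.uint8)
    return float(np.mean(arr_a != arr_b))


def gen_strain_library(
    seed: int,
    n_reference: int = 7,
    n_indigenous: int = 4,
    its_len: int = 461,
    clade_divergence: float = 0.10,
) -> StrainLibrary:
    """Generate a reference strain library with known phylogenetic structure.

    Reference strains split into two clades (first ~5 tags vs the rest),
    indigenous strains form a third deep-branching cluster, and an outgroup
    is attached far enough that its distance to every library member exceeds
    the maximum within-library distance. ERIC band profiles are pairwise
    disjoint (Dice < 0.8 at zero tolerance) while one designated pair of
    reference strains shares a near-identical BOX profile (Dice > 0.9),
    mirroring a typing system in which one primer discriminates better than
    the other.

    Parameters
    ----------
    clade_divergence : float
        Expected between-clade distance in substitutions/site, in [0, 0.75).
        All branch lengths of the generating tree scale with it; zero yields
        identical sequences.
    """
    if n_reference < 2:
        raise ValueError("n_reference must be >= 2")
    if n_reference > 26 or n_indigenous < 0:
        raise ValueError("n_reference must be <= 26 and n_indigenous >= 0")
    if its_len < 200:
        raise ValueError("its_len must be >= 200")
    if not (0.0 <= clade_divergence < _JC_SATURATION):
        raise ValueError("clade_divergence must lie in [0, 0.75)")

    rng = np.random.default_rng(seed)
    d = clade_divergence
    tags = list(string.ascii_uppercase[:n_reference])
    ref_ids = [
        _REFERENCE_IDS[i] if i < len(_REFERENCE_IDS) else f"ref-{tags[i]}"
        for i in range(n_reference)
    ]
    n_clade1 = max(1, min(5, n_reference - 2)) if n_reference > 2 else 1
    clades = ["reference-1"] * n_clade1 + ["reference-2"] * (n_reference - n_clade1)
    ind_ids = [f"KAV-{i + 1}" for i in range(n_indigenous)]

    # -- ITS sequences: Jukes-Cantor evolution along a fixed known tree -----
    root = rng.integers(0, 4, size=its_len)
    anc_c1 = _jc_evolve(root, d / 2.0, rng)
    anc_c2 = _jc_evolve(root, d / 2.0, rng)
    anc_ind = _jc_evolve(root, 1.2 * d, rng)
    tip_len = d / 6.0
    ref_seqs = [
        _decode(_jc_evolve(anc_c1 if clades[i] == "reference-1" else anc_c2, tip_len, rng))
        for i in range(n_reference)
    ]
    ind_seqs = [_decode(_jc_evolve(anc_ind, tip_len, rng)) for _ in range(n_indigenous)]
    out_seq = _decode(_jc_evolve(root, 3.0 * d, rng))

    # -- band profiles: disjoint draws from widely spaced pools -------------
    # One pool per method (ERIC and BOX profiles are never compared with each
    # other); within a method the strains draw disjoint band sets, so every
    # cross-strain Dice similarity is 0 at zero tolerance.
    n_taxa = n_reference + n_indigenous + 1
    slots = np.arange(100, 5000, _BAND_POOL_SPACING)
    if 11 * n_taxa > slots.size:
        raise ValueError("too many taxa for distinguishable synthetic band profiles")

    def make_pool() -> "itertools.chain":
        return iter(slots[rng.permutation(slots.size)].tolist())

    eric_pool, box_pool = make_pool(), make_pool()

    def draw_bands(pool, k: int) -> list[int]:
        return sorted(itertools.islice(pool, k))

    eric = [draw_bands(eric_pool, int(rng.integers(6, 10))) for _ in range(n_taxa)]
    box = [draw_bands(box_pool, int(rng.integers(7, 11))) for _ in range(n_taxa)]
    # designated near-identical BOX pair: tags B and E when present
    if n_reference >= 5:
        i_src, i_dst = 1, 4  # B, E
    else:
        i_src, i_dst = n_reference - 2, n_reference - 1
    box[i_dst] = sorted(box[i_src] + draw_bands(box_pool, 1))

    strains = [
        StrainProfile(
            id=ref_ids[i],
            tag=tags[i],
            eric_bands=eric[i],
            box_bands=box[i],
            its_seq=ref_seqs[i],
            clade=clades[i],
        )
        for i in range(n_reference)
    ]
    strains += [
        StrainProfile(
            id=ind_ids[j],
            tag=None,
            eric_bands=eric[n_reference + j],
            box_bands=box[n_reference + j],
            its_seq=ind_seqs[j],
            clade="novel-indigenous",
        )
        for j in range(n_indigenous)
    ]
    outgroup = StrainProfile(
        id="OUTGROUP",
        tag=None,
        eric_bands=eric[-1],
        box_bands=box[-1],
        its_seq=out_seq,
        clade="outgroup",
    )
    library = StrainLibrary(strains=strains, outgroup=outgroup)

    if d > 0:
        max_within = max(
            _p_distance(a.its_seq, b.its_seq)
            for a, b in itertools.combinations(library.strains, 2)
        )
        min_out = min(_p_distance(s.its_seq, out_seq) for s in library.strains)
        if min_out <= max_within:
            raise RuntimeError(
                "outgroup landed closer than the deepest within-library split; "
                "increase its_len or lower clade_divergence"
            )
    return library


# ---------------------------------------------------------------------------
# competition samples
# ---------------------------------------------------------------------------


def gen_competition_samples(
    library: StrainLibrary, scenario: CompetitionScenario
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-experiment inoculum and nodule strain counts.

    Per experiment the realized starter mix ``p*`` is a Dirichlet draw around
    equal proportions; inoculum colony counts are multinomial(n_colonies, p*)
    and nodule counts are multinomial(n_nodules, q) with q proportional to
    p* x weights. Returns two DataFrames (experiments x tags); each frame
    carries the realized mixes in ``attrs["realized_mix"]`` as hidden truth.
    """
    tags = library.tags
    if set(scenario.weights) != set(tags):
        raise ValueError(
            f"scenario weights keyed by {sorted(scenario.weights)} do not match "
            f"library reference tags {tags}"
        )
    w = np.array([scenario.weights[t] for t in tags], dtype=float)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    S = len(tags)
    rng = np.random.default_rng(scenario.seed)
    alpha = scenario.inoculum_dirichlet_concentration * np.full(S, 1.0 / S)
    inoc_rows, nod_rows, mixes = [], [], []
    for _ in range(scenario.n_experiments):
        p_star = rng.dirichlet(alpha)
        q = p_star * w
        q_sum = q.sum()
        if q_sum <= 0:
            raise ValueError("weights and realized mix leave no strain able to nodulate")
        q = q / q_sum
        inoc_rows.append(rng.multinomial(scenario.n_colonies, p_star))
        nod_rows.append(rng.multinomial(scenario.n_nodules, q))
        mixes.append(p_star)
    idx = pd.RangeIndex(1, scenario.n_experiments + 1, name="experiment")
    inoc = pd.DataFrame(inoc_rows, index=idx, columns=tags)
    nod = pd.DataFrame(nod_rows, index=idx, columns=tags)
    inoc.attrs["realized_mix"] = np.array(mixes)
    nod.attrs["realized_mix"] = np.array(mixes)
    return inoc, nod


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------


def gen_trait_table(
    effects: TraitEffects,
    n_blocks: int = 3,
    n_experiments: int = 3,
    seed: int = 0,
    varieties: tuple[str, ...] = VARIETIES,
    treatments: tuple[str, ...] = TREATMENTS,
) -> pd.DataFrame:
    """Generate a balanced RCBD factorial trait table (long format).

    One row per variety x treatment x block x experiment x trait. Values are
    cell mean + block effect (Gaussian, redrawn per block and experiment) +
    Gaussian residual. Count traits are rounded, clipped at zero, and forced
    to exactly zero for structural-zero cells.
    """
    if n_blocks < 2:
        raise ValueError("n_blocks must be >= 2")
    if n_experiments < 1:
        raise ValueError("n_experiments must be >= 1")
    rng = np.random.default_rng(seed)
    zero_cells = set(effects.structural_zero_rules)
    rows = []
    for trait in effects.traits:
        b_eff = rng.normal(0.0, effects.block_sd[trait], size=(n_experiments, n_blocks))
        for e in range(1, n_experiments + 1):
            for b in range(1, n_blocks + 1):
                for v in varieties:
                    for t in treatments:
                        is_count = trait in effects.count_traits
                        if is_count and (v, t) in zero_cells:
                            val = 0.0
                        else:
                            val = (
                                effects.cell_mean(trait, v, t)
                                + b_eff[e - 1, b - 1]
                                + rng.normal(0.0, effects.residual_sd[trait])
                            )
                            if is_count:
                                val = float(max(0.0, round(val)))
                        rows.append((v, t, b, e, trait, val))
    return pd.DataFrame(
        rows, columns=["variety", "treatment", "block", "experiment", "trait", "value"]
    )


# ---------------------------------------------------------------------------
# fingerprint observations
# ---------------------------------------------------------------------------


def gen_fingerprint_observations(
    library: StrainLibrary,
    counts: pd.DataFrame,
    band_jitter_bp: int = 0,
    seed: int = 0,
    source: str = "nodule",
    variety: str = "red",
    treatment: str = "MK",
) -> pd.DataFrame:
    """Expand a counts table into per-isolate band observations with jitter.

    Each isolate inherits its true strain's ERIC and BOX band lists with every
    band perturbed by a uniform integer offset in [-jitter, +jitter]. The true
    tag rides along in the ``true_tag`` column as hidden evaluation truth; the
    typing stage must never read it.
    """
    if band_jitter_bp < 0:
        raise ValueError("band_jitter_bp must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for exp, row in counts.iterrows():
        for tag in counts.columns:
            profile = library.by_tag(tag)
            for _ in range(int(row[tag])):
                k += 1

                def jitter(bands: list[int]) -> list[int]:
                    if band_jitter_bp == 0:
                        return list(bands)
                    offs = rng.integers(-band_jitter_bp, band_jitter_bp + 1, len(bands))
                    return sorted(int(b + o) for b, o in zip(bands, offs))

                rows.append(
                    {
                        "isolate_id": f"{source[:3]}-{variety}-{exp}-{k:03d}",
                        "source": source,
                        "variety": variety,
                        "treatment": treatment,
                        "experiment": exp,
                        "eric_bands": jitter(profile.eric_bands),
                        "box_bands": jitter(profile.box_bands),
                        "true_tag": tag,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "isolate_id",
            "source",
            "variety",
            "treatment",
            "experiment",
            "eric_bands",
            "box_bands",
            "true_tag",
        ],
    )
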