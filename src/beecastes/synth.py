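"""Synthetic data with known ground truth, plus the packaged study fixture.

The raw individual-level measurements behind the 28-species survey are not
redistributable, so every pipeline input can be generated here instead:
colony-structured head-width/weight/melanization samples with a chosen
differentiation index, Brownian-motion continuous traits on a tree, and
binary trait pairs evolving under independent or dependent Markov models.
Defaults mirror the study's sampling design (2-8 colonies and roughly 70
workers per species).

The study fixture bundles (i) a transcription of the published
species-level summary table (28 species: means, CVs, DIs, adjusted test
statistics, robber-bee target flags) and (ii) a genus-level chronogram.
The fixture topology is synthetic: it is hand-built to match the genus
relationships the study describes, with within-genus divergences settable
(2 my by default, near-zero in the alternative variant); its deep branch
lengths are plausible values, not published estimates.
"""
from __future__ import annotations

import dataclasses
import hashlib
import importlib.resources
import io
import json
import math
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import phylo
from .phylo import BinaryStateVector, PhyloTree, simulate_discrete
from .comparative import _pagel_Q

REFERENCE_CSV = "species_summary_reference.csv"
REFERENCE_SHA256 = "4fd0a38fce2fda3794c086018e1336fa667def546f0873ee498a8b3763821ab4"

#: fixed seed offsets for deriving per-task streams from one master seed
SEED_OFFSETS = {"colonies": 11, "bm": 23, "binary": 37, "mapping": 53, "pagel": 71}
_SEED_MOD = 2**31 - 1


def derive_seed(master_seed: int, task: str) -> int:
    """Per-task seed from a master seed by fixed offsets (stable, < 2^31)."""
    return (int(master_seed) * 1000 + SEED_OFFSETS[task]) % _SEED_MOD


# ---------------------------------------------------------------------------
# Colony-structured morphometric samples
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class SpeciesGeneratorSpec:
    """Ground-truth parameters for one synthetic species.

    Defaults follow the study's sampling design: about 4 colonies and 70
    workers per species, forager head widths around 2 mm with a
    within-colony CV of 0.02, and colony-to-colony intercept spread of
    0.03 mm. ``di`` is the target population differentiation index;
    ``bimodal`` draws guards from a separated second mode with its own
    spread rather than shifting the common distribution.
    """

    species: str = "synthetic"
    n_colonies: int = 4
    n_guards_target: int = 8
    n_foragers_target: int = 10
    forager_mean_mm: float = 2.0
    cv: float = 0.02
    di: float = 0.0
    bimodal: bool = False
    guard_mode_sd_factor: float = 0.8
    colony_sd_mm: float = 0.03
    melanization_forager: Optional[float] = None
    melanization_guard: Optional[float] = None
    melanization_sd: float = 0.03
    reference_gray: float = 200.0
    allometry_slope: Optional[float] = None
    weight_mean_mg: float = 10.0
    weight_log10_noise_sd: float = 0.03
    lestrimelitta_target: bool = False

    def __post_init__(self) -> None:
        if self.di < 0 or self.cv < 0:
            raise ValueError("di and cv must be >= 0")
        if not 2 <= self.n_colonies <= 8:
            raise ValueError("n_colonies must lie in 2..8")
        if self.forager_mean_mm <= 0:
            raise ValueError("forager_mean_mm must be > 0")


def _guard_offset(spec: SpeciesGeneratorSpec) -> Tuple[float, float, float]:
    """Solve the guard-mode offset giving the target population DI.

    With forager/guard within-colony spreads sigma_f, sigma_g, mixture
    proportions p_f, p_g and offset delta, the pooled within-colony sd is
    sqrt(p_f sigma_f^2 + p_g sigma_g^2 + p_f p_g delta^2), so
    delta = DI * s / sqrt(1 - DI^2 p_f p_g), s^2 the variance part.
    """
    sigma_f = spec.cv * spec.forager_mean_mm
    sigma_g = sigma_f * (spec.guard_mode_sd_factor if spec.bimodal else 1.0)
    ng, nf = spec.n_guards_target, spec.n_foragers_target
    p_g = ng / (ng + nf)
    p_f = 1.0 - p_g
    s2 = p_f * sigma_f**2 + p_g * sigma_g**2
    if spec.di == 0:
        return 0.0, sigma_f, sigma_g
    if s2 == 0:
        raise ValueError("target DI > 0 is infeasible with zero within-colony spread")
    denom = 1.0 - spec.di**2 * p_f * p_g
    if denom <= 0:
        raise ValueError(f"target DI {spec.di} infeasible for role mix "
                         f"p_guard={p_g:.2f} (needs DI^2 < 1/(p_f*p_g))")
    delta = spec.di * math.sqrt(s2 / denom)
    return delta, sigma_f, sigma_g


def generate_colony_dataset(spec: SpeciesGeneratorSpec,
                            seed: Optional[int] = None) -> pd.DataFrame:
    """Simulate an individual-level morphometric table for one species.

    Head widths are colony intercept + role mean + Gaussian noise, with the
    guard offset solved so the constructed population DI equals
    ``spec.di``. Per-colony role counts are max(2, Poisson(target)).
    Wet weights follow head_width^(3/b) scaling with log10 noise when
    ``allometry_slope`` is set; gray levels are generated directly from the
    role melanization means when they are set.
    """
    rng = np.random.default_rng(seed)
    delta, sigma_f, sigma_g = _guard_offset(spec)
    rows: List[dict] = []
    bee = 0
    for ci in range(spec.n_colonies):
        colony = f"{spec.species}_c{ci + 1}"
        intercept = rng.normal(0.0, spec.colony_sd_mm)
        n_g = max(2, int(rng.poisson(spec.n_guards_target)))
        n_f = max(2, int(rng.poisson(spec.n_foragers_target)))
        for role, n, mu, sd in (("forager", n_f, spec.forager_mean_mm, sigma_f),
                                ("guard", n_g, spec.forager_mean_mm + delta, sigma_g)):
            hw = rng.normal(mu + intercept, sd, size=n)
            hw = np.maximum(hw, 0.05)
            if spec.allometry_slope is not None:
                b = spec.allometry_slope
                eps = rng.normal(0.0, spec.weight_log10_noise_sd, size=n)
                w = ((hw / spec.forager_mean_mm) ** (3.0 / b)
                     * spec.weight_mean_mg * 10.0 ** eps)
            else:
                w = np.full(n, np.nan)
            if spec.melanization_forager is not None:
                m = (spec.melanization_guard if role == "guard"
                     else spec.melanization_forager)
                mval = rng.normal(m, spec.melanization_sd, size=n)
                gray = spec.reference_gray * (1.0 - mval)
                ref = np.full(n, spec.reference_gray)
            else:
                gray = np.full(n, np.nan)
                ref = np.full(n, np.nan)
            for i in range(n):
                bee += 1
                rows.append({
                    "species": spec.species, "colony": colony,
                    "bee_id": f"{spec.species}_b{bee}", "role": role,
                    "head_width_mm": hw[i], "wet_weight_mg": w[i],
                    "gray_level": gray[i], "reference_gray": ref[i],
                    "cuticle_um": np.nan,
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Trait evolution on trees
# ---------------------------------------------------------------------------

def simulate_bm_traits(tree: PhyloTree, sigma2: float, root_value: float = 0.0,
                       seed: Optional[int] = None) -> Dict[str, float]:
    """Brownian-motion tip values: Gaussian increments with variance sigma2 * b."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be > 0")
    tree.require_lengths()
    rng = np.random.default_rng(seed)
    x = np.zeros(tree.n_nodes)
    x[tree.root] = root_value
    for v in tree.preorder:
        if v == tree.root:
            continue
        x[v] = x[tree.parent[v]] + rng.normal(0.0, math.sqrt(sigma2 * tree.length[v]))
    return {l: float(x[tree.tip_id(l)]) for l in tree.tip_labels}


def simulate_binary_pair(tree: PhyloTree, mode: str = "independent",
                         rates: Optional[Dict[str, float]] = None,
                         seed: Optional[int] = None,
                         max_resample: int = 50
                         ) -> Tuple[BinaryStateVector, BinaryStateVector, bool]:
    """Two binary traits evolved jointly on the tree; returns (A, B, ok).

    ``mode='independent'`` takes 4 rates (qA01, qA10, qB01, qB10);
    ``mode='dependent'`` takes the 8 context-specific rates of the joint
    chain. A draw where either trait comes out constant is resampled up to
    ``max_resample`` times; ``ok=False`` flags exhaustion.
    """
    if rates is None:
        rates = {"qA01": 0.02, "qA10": 0.02, "qB01": 0.02, "qB10": 0.02}
    if mode == "independent":
        r = {"qA01_B0": rates["qA01"], "qA01_B1": rates["qA01"],
             "qA10_B0": rates["qA10"], "qA10_B1": rates["qA10"],
             "qB01_A0": rates["qB01"], "qB01_A1": rates["qB01"],
             "qB10_A0": rates["qB10"], "qB10_A1": rates["qB10"]}
    elif mode == "dependent":
        r = dict(rates)
    else:
        raise ValueError("mode must be 'independent' or 'dependent'")
    if any(v < 0 for v in r.values()):
        raise ValueError("rates must be >= 0")
    Q = _pagel_Q(**r)
    rng = np.random.default_rng(seed)
    for _ in range(max_resample):
        hist = simulate_discrete(tree, Q, root_prior="equal", rng=rng)
        tips = hist.tip_states()
        a = {k: v // 2 for k, v in tips.items()}
        b = {k: v % 2 for k, v in tips.items()}
        A = BinaryStateVector(a, "trait A")
        B = BinaryStateVector(b, "trait B")
        if not A.is_constant() and not B.is_constant():
            return A, B, True
    return A, B, False


def random_bifurcating_tree(n_tips: int, seed: Optional[int] = None,
                            ultrametric: bool = False) -> PhyloTree:
    """Random bifurcating tree with exponential(mean 1) branch lengths.

    Coalescent-style construction: tip lineages are merged in random pairs.
    With ``ultrametric=True`` node heights accumulate so every tip is
    equidistant from the root (for chronogram-like tests).
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    parts = [f"t{i + 1}" for i in range(n_tips)]
    if ultrametric:
        heights = [0.0] * n_tips
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            h = max(heights[i], heights[j]) + float(rng.exponential(1.0))
            a = f"({parts[i]}:{h - heights[i]:.10g},{parts[j]}:{h - heights[j]:.10g})"
            parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [a]
            heights = [x for k, x in enumerate(heights) if k not in (i, j)] + [h]
        return phylo.parse_newick(parts[0] + ":0;")
    while len(parts) > 1:
        i, j = sorted(rng.choice(len(parts), size=2, replace=False))
        bi, bj = rng.exponential(1.0, size=2)
        a = f"({parts[i]}:{bi:.10g},{parts[j]}:{bj:.10g})"
        parts = [p for k, p in enumerate(parts) if k not in (i, j)] + [a]
    return phylo.parse_newick(parts[0] + ":0;")


# ---------------------------------------------------------------------------
# The study fixture
# ---------------------------------------------------------------------------

def tip_label(species: str) -> str:
    """Species binomial to tree tip label (underscored, punctuation dropped)."""
    return species.replace(".", "").replace(" ", "_")


# (name, age in my, children); ages are node heights above the present.
# Within-genus splits marked "d" take the user-set divergence (default 2 my).
def _fixture_topology(d: float):
    return ("root", 76, [
        ("melipona_clade", 23, [
            ("m1", 18, ["Melipona fasciculata", "Melipona flavolineata"]),
            ("m2", 9, ["Melipona melanoventer",
                       ("m3", 8, ["Melipona scutellaris", "Melipona subnitida"])]),
        ]),
        ("n1", 64, [
            ("minute_clade", 30, ["Leurotrigona muelleri", "Trigonisca nataliae"]),
            ("n2", 60, [
                ("plebeia_group", 47, [
                    ("p1", 38, ["Friesella schrottkyi",
                                ("p2", 7, ["Plebeia droryana",
                                           ("tetragonisca", d,
                                            ["Tetragonisca angustula",
                                             "Tetragonisca fiebrigi"])])]),
                    ("p3", 38, ["Lestrimelitta limao",
                                ("frieseomelitta", d, [
                                    ("f1", d / 2, ["Frieseomelitta varia",
                                                   "Frieseomelitta silvestrii"]),
                                    ("f2", d / 2, ["Frieseomelitta flavicornis",
                                                   "Frieseomelitta longipes"])])]),
                ]),
                ("trigona_group", 35, [
                    ("t1", 34, [
                        ("t2", 14, ["Paratrigona lineata",
                                    "Nannotrigona testaceicornis"]),
                        ("t3", 19, ["Scaura latitarsis", "Partamona helleri"]),
                    ]),
                    ("t4", 24, [
                        ("scaptotrigona", d, ["Scaptotrigona bipunctata",
                                              ("s1", d / 2,
                                               ["Scaptotrigona aff. depilis",
                                                "Scaptotrigona tubiba"])]),
                        ("t5", 23, [
                            ("t6", 11, ["Geotrigona mombuca", "Tetragona clavipes"]),
                            ("trigona", 13, ["Trigona recursa",
                                             ("t7", 8, ["Trigona fuscipennis",
                                                        "Trigona hypogea"])]),
                        ]),
                    ]),
                ]),
            ]),
        ]),
    ])

def fixture_tree(within_genus_divergence: float = 2.0) -> PhyloTree:
    """The packaged 28-tip chronogram (genus-level topology, ultrametric).

    ``within_genus_divergence`` sets the Tetragonisca, Frieseomelitta and
    Scaptotrigona species splits (2 my default; pass ~1e-6 for the
    near-zero robustness variant). Deep node ages are synthetic choices.
    """
    d = within_genus_divergence

    def newick(node, parent_age):
        if isinstance(node, str):
            return f"{tip_label(node)}:{parent_age:.8g}"
        name, age, kids = node
        inner = ",".join(newick(k, age) for k in kids)
        blen = f":{parent_age - age:.8g}" if parent_age is not None else ":0"
        return f"({inner}){blen}"

    text = newick(_fixture_topology(d), None) + ";"
    return phylo.parse_newick(text)


@dataclasses.dataclass
class StudyFixture:
    """Species-level reference table, fixture chronogram and binary vectors."""

    table: pd.DataFrame
    tree: PhyloTree
    tree_alternative: PhyloTree
    larger_guards: BinaryStateVector
    lestrimelitta_target: BinaryStateVector
    alpha: float = 0.05


def load_reference_table() -> pd.DataFrame:
    """Load (and checksum-verify) the packaged species-level summary table.

    The adjusted guard-test p column keeps the table's printed form
    (including '<0.0001'); a numeric ``p_guards_num`` column parses bounds
    at their printed value.
    """
    res = importlib.resources.files("beecastes").joinpath(f"data/{REFERENCE_CSV}")
    raw = res.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != REFERENCE_SHA256:
        raise ValueError(f"packaged reference table checksum mismatch: {digest}")
    df = pd.read_csv(io.BytesIO(raw), dtype={"p_guards_adj": str})
    df["p_guards_num"] = df["p_guards_adj"].str.lstrip("<").astype(float)
    df["genus"] = df["species"].str.split().str[0]
    df["lestrimelitta_target"] = df["lestrimelitta_target"].map(
        {"yes": True, "no": False})
    return df


def build_study_fixture(within_genus_divergence: float = 2.0,
                        alpha: float = 0.05) -> StudyFixture:
    """Assemble the packaged fixture: table, chronogram and binary vectors.

    ``larger_guards`` is derived from the table's adjusted p-values
    (p <= alpha and guard mean above forager mean); the robber-bee target
    vector comes from the survey column.
    """
    df = load_reference_table()
    larger = (df["p_guards_num"] <= alpha) & (df["size_difference_pct"] > 0)
    df = df.assign(larger_guards=larger)
    tree = fixture_tree(within_genus_divergence)
    tree_alt = fixture_tree(phylo.BRANCH_LENGTH_FLOOR)
    if set(tip_label(s) for s in df["species"]) != set(tree.tip_labels):
        raise ValueError("fixture tree tips do not match the reference table")
    lg = BinaryStateVector({tip_label(s): int(v) for s, v in
                            zip(df["species"], larger)},
                           "guards of increased size")
    tg = BinaryStateVector({tip_label(s): int(v) for s, v in
                            zip(df["species"], df["lestrimelitta_target"])},
                           "target of Lestrimelitta")
    return StudyFixture(df, tree, tree_alt, lg, tg, alpha)


def write_manifest(path, params: dict) -> None:
    """Record every generator parameter and seed for a simulation run."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
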