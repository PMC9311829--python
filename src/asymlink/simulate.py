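"""Synthetic studies with known ground truth.

No raw data ship with the study this pipeline operationalizes, so the
generator emulates its structure end to end: bilaterally symmetric
landmark configurations (20/6 landmarks for fore-/hindwings under
matching symmetry, 29 for heads under object symmetry) with separate
individual-shape, fluctuating-asymmetry and two nested measurement-
error variance strata; multilocus microsatellite genotypes under a
chosen inbreeding coefficient F; and pooled body-burden tables whose
concentrations span the published ranges.  Every generator is a pure
function of its configuration (seed included), so downstream stages
have exact parameter-recovery tests.

The landmark model, per coordinate in shape (tangent) space before the
similarity transform of each photograph:

    x = template + individual deviation (sd_individual)
        +/- FA deviation (sd_fa; opposite sign on opposite sides)
        +/- directional asymmetry (sd_da, one fixed vector)
        + per-image noise (sd_image) + per-digitization noise (sd_digit)

so the side-by-individual interaction variance component equals
``sd_fa**2`` per coordinate and nested-ANOVA expected-mean-square
identities recover it.  In object mode the individual deviation is
projected onto the symmetric subspace and the FA deviation onto the
asymmetric subspace (rescaled so the per-dimension variance is
preserved).  An optional positive control couples the per-pool FA
scales to the pool's PCB burden -- a variance, not mean, effect,
because FA is a variance phenomenon.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .landmark_io import LandmarkConfiguration, LandmarkDataset, write_tps
from .popgen import GenotypeTable
from .procrustes import centroid_size, reflect

__all__ = [
    "SyntheticConfig",
    "default_pairing",
    "make_landmarks",
    "make_genotypes",
    "StudyBundle",
    "make_study",
    "default_burdens",
]


def default_pairing(p: int = 13, m: int = 3):
    """A consistent left/right pairing scheme for a 2p+m object-symmetric structure.

    Landmarks 1..p are the left-side points, p+1..2p their right-side
    partners, and 2p+1..2p+m lie on the midline.  (The published head
    scheme does not print its pairing; this is the package's own
    consistent convention.)
    """
    pairs = [(j + 1, p + j + 1) for j in range(p)]
    midline = [2 * p + j + 1 for j in range(m)]
    return pairs, midline


def _matching_template(k: int) -> np.ndarray:
    t = 2.0 * np.pi * np.arange(k) / k
    r = 1.0 + 0.35 * np.sin(2.0 * t + 0.8) + 0.15 * np.cos(5.0 * t + 0.3)
    pts = np.column_stack([r * np.cos(t), r * np.sin(t)])
    pts -= pts.mean(axis=0)
    return pts / centroid_size(pts)


def _object_template(pairs, midline, k: int) -> np.ndarray:
    p, m = len(pairs), len(midline)
    xs = 0.25 + 0.6 * ((np.arange(p) * 37) % p) / max(p, 1)
    ys = -1.0 + 2.0 * np.arange(p) / max(p - 1, 1)
    right = np.column_stack([xs, ys])
    left = right * np.array([-1.0, 1.0])
    mids = np.column_stack([np.zeros(m), -1.2 + 2.5 * np.arange(m) / max(m - 1, 1)])
    pts = np.empty((k, 2))
    for (li, ri), lpt, rpt in zip(pairs, left, right):
        pts[li - 1] = lpt
        pts[ri - 1] = rpt
    for idx, mpt in zip(midline, mids):
        pts[idx - 1] = mpt
    pts -= pts.mean(axis=0)
    return pts / centroid_size(pts)


@dataclass
class SyntheticConfig:
    """Ground-truth parameters for one synthetic landmark dataset.

    Scales are standard deviations per landmark coordinate in unit-
    centroid-size shape space; ``sd_size``/``sd_size_fa`` govern the
    log-normal individual size and the relative right-left size
    asymmetry that feeds the FA2 index.
    """

    seed: int
    n_individuals: int = 30
    k: int = 10
    symmetry_mode: str = "matching"
    pairing: list = field(default_factory=list)
    midline: list = field(default_factory=list)
    sd_individual: float = 0.03
    sd_fa: float = 0.01
    sd_da: float = 0.0
    sd_image: float = 0.0
    sd_digit: float = 0.002
    n_image_rep: int = 1
    n_digit_rep: int = 1
    mean_size: float = 10.0
    sd_size: float = 0.08
    sd_size_fa: float = 0.01
    location: str | None = None
    nest: str | None = None
    species: str | None = None
    id_prefix: str = "ind"
    inbreeding_f: float = 0.0
    n_loci: int = 7

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.k < 3:
            raise ValueError("need at least 3 landmarks")
        for name in ("sd_individual", "sd_fa", "sd_da", "sd_image", "sd_digit",
                     "sd_size", "sd_size_fa"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.inbreeding_f <= 1.0:
            raise ValueError("inbreeding_f must lie in [0, 1]")
        if self.symmetry_mode == "object" and not self.pairing:
            pairs, midline = default_pairing((self.k - 3) // 2, self.k - 2 * ((self.k - 3) // 2))
            self.pairing, self.midline = pairs, midline


def _photo_transform(rng):
    theta = rng.uniform(0.0, 2.0 * np.pi)
    c, s = np.cos(theta), np.sin(theta)
    rot = np.array([[c, -s], [s, c]])
    shift = rng.uniform(-5.0, 5.0, size=2)
    return rot, shift


def make_landmarks(config: SyntheticConfig, per_individual_fa_scale=None) -> LandmarkDataset:
    """Generate a landmark dataset under the configured variance strata.

    ``per_individual_fa_scale`` optionally multiplies ``sd_fa`` and
    ``sd_size_fa`` per individual (a mapping from individual number,
    0-based, to a factor) -- the hook the pooled-burden positive
    control uses.  Deterministic given the config.
    """
    rng = np.random.default_rng(config.seed)
    mode = config.symmetry_mode
    k = config.k
    if mode == "matching":
        template = _matching_template(k)
    elif mode == "object":
        template = _object_template(config.pairing, config.midline, k)
        perm = np.arange(k)
        for left, right in config.pairing:
            perm[left - 1], perm[right - 1] = right - 1, left - 1
        left_idx = np.array([pair[0] - 1 for pair in config.pairing])
        right_idx = np.array([pair[1] - 1 for pair in config.pairing])

        def sym_part(x):
            return (x + reflect(x, "y")[perm]) / 2.0

        def asym_part(x):
            return (x - reflect(x, "y")[perm]) / 2.0
    else:
        raise ValueError(f"unknown symmetry mode {mode!r}")

    da_raw = rng.normal(0.0, config.sd_da, (k, 2)) if config.sd_da > 0 else np.zeros((k, 2))
    if mode == "object" and config.sd_da > 0:
        da_raw = asym_part(da_raw)

    configs = []
    for i in range(config.n_individuals):
        fa_factor = 1.0
        if per_individual_fa_scale is not None:
            fa_factor = float(per_individual_fa_scale.get(i, 1.0))
        ind_id = f"{config.id_prefix}{i + 1:03d}"
        dev = rng.normal(0.0, config.sd_individual, (k, 2))
        fa_dev = rng.normal(0.0, config.sd_fa * fa_factor, (k, 2))
        if mode == "object":
            dev = sym_part(dev) * np.sqrt(2.0)
            # no sqrt(2) boost: the mirrored-copy analysis counts the
            # asymmetric deviation on both copies, so the plain
            # projection already yields an FA variance component of
            # sd_fa**2 per coordinate under the EMS identity
            fa_dev = asym_part(fa_dev)
        size_i = config.mean_size * np.exp(rng.normal(0.0, config.sd_size))
        delta = rng.normal(0.0, config.sd_size_fa * fa_factor)

        if mode == "matching":
            # the antisymmetric deviation is split over the two sides
            # (factor 1/sqrt(2)) so the side-by-individual interaction
            # variance component equals sd_fa**2 per coordinate exactly
            asym = (fa_dev + da_raw) / np.sqrt(2.0)
            bases = {
                "right": (template + dev + asym, size_i * (1.0 + delta / 2.0)),
                "left": (template + dev - asym, size_i * (1.0 - delta / 2.0)),
            }
        else:
            shape = template + dev + fa_dev + da_raw
            # inject left/right subset-size asymmetry by scaling each
            # half about its own centroid
            shape = shape.copy()
            for idx, factor in ((left_idx, 1.0 - delta / 2.0), (right_idx, 1.0 + delta / 2.0)):
                centroid = shape[idx].mean(axis=0)
                shape[idx] = centroid + factor * (shape[idx] - centroid)
            bases = {"none": (shape, size_i)}

        for side, (base, size_side) in bases.items():
            for j in range(1, config.n_image_rep + 1):
                img_dev = (
                    rng.normal(0.0, config.sd_image, (k, 2)) if config.sd_image > 0 else 0.0
                )
                photo_base = base + img_dev
                # digitizing replicates re-measure the same photograph,
                # so they share its similarity transform
                rot, shift = _photo_transform(rng)
                for r in range(1, config.n_digit_rep + 1):
                    digit_dev = (
                        rng.normal(0.0, config.sd_digit, (k, 2)) if config.sd_digit > 0 else 0.0
                    )
                    shape_r = photo_base + digit_dev
                    if side == "left":
                        shape_r = reflect(shape_r, "y")
                    coords = size_side * shape_r @ rot.T + shift
                    classifiers = {
                        "individual": ind_id,
                        "side": side,
                        "image_rep": j,
                        "digit_rep": r,
                    }
                    for label in ("location", "nest", "species"):
                        value = getattr(config, label)
                        if value is not None:
                            classifiers[label] = value
                    configs.append(
                        LandmarkConfiguration(
                            specimen_id=f"{ind_id}_{side}_i{j}_d{r}",
                            coords=coords,
                            classifiers=classifiers,
                        )
                    )
    return LandmarkDataset(
        configs=configs,
        symmetry_mode=mode,
        pairing=list(config.pairing),
        midline=list(config.midline),
    )


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def _default_locus_specs(n_loci: int):
    specs = []
    base_freqs = np.array([0.35, 0.25, 0.20, 0.12, 0.08])
    for j in range(n_loci):
        freqs = np.roll(base_freqs, j % len(base_freqs))
        n_alleles = 4 + (j % 2)
        f = freqs[:n_alleles] / freqs[:n_alleles].sum()
        alleles = np.arange(8 + j, 8 + j + n_alleles)  # repeat counts
        specs.append({"name": f"loc{j + 1:02d}", "alleles": alleles, "freqs": f, "motif": 2})
    return specs


def make_genotypes(config: SyntheticConfig, ids=None, groups: pd.DataFrame | None = None,
                   loci=None) -> GenotypeTable:
    """Diploid microsatellite genotypes under inbreeding coefficient F.

    Per individual and locus, with probability F both alleles are one
    identical-by-descent draw from the allele-frequency spectrum,
    otherwise two independent draws.  Deterministic given the config
    seed (offset so landmark and genotype streams are independent).
    """
    rng = np.random.default_rng((config.seed + 104729) % 2**31)
    n = config.n_individuals
    if ids is None:
        ids = [f"{config.id_prefix}{i + 1:03d}" for i in range(n)]
    loci = loci if loci is not None else _default_locus_specs(config.n_loci)
    a1 = {}
    a2 = {}
    motifs = {}
    F = config.inbreeding_f
    for spec in loci:
        freqs = np.asarray(spec["freqs"], dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{spec['name']}: allele frequencies sum to {freqs.sum()}, not 1")
        alleles = np.asarray(spec["alleles"], dtype=float)
        draw = rng.choice(alleles, size=(n, 2), p=freqs)
        ibd = rng.random(n) < F
        draw[ibd, 1] = draw[ibd, 0]
        a1[spec["name"]] = draw[:, 0]
        a2[spec["name"]] = draw[:, 1]
        motifs[spec["name"]] = spec.get("motif", 1)
    index = pd.Index(ids, name="individual")
    if groups is None:
        groups = pd.DataFrame(index=index)
    else:
        groups = groups.set_axis(index)
    return GenotypeTable(
        a1=pd.DataFrame(a1, index=index),
        a2=pd.DataFrame(a2, index=index),
        groups=groups,
        motifs=motifs,
    )


# ---------------------------------------------------------------------------
# Whole-study bundles
# ---------------------------------------------------------------------------

#: pooled samples mirroring the published study layout: one bumblebee
#: pool per location plus one pool per ant species and location, with
#: Hg and summed-PCB levels spanning the printed concentration ranges
#: (µg/kg fresh weight).
_POOLS = [
    # pool_id, location, taxon, Hg, sum of the six indicator PCBs
    ("pool1", "Zugspitze", "Bombus", 7.8, 1.50),
    ("pool2", "Zugspitze", "F_aquilonia", 7.8, 0.46),
    ("pool3", "Zugspitze", "F_exsecta", 7.0, 0.93),
    ("pool4", "HoherSonnblick", "Bombus", 1.2, 0.39),
    ("pool5", "HoherSonnblick", "F_aquilonia", 11.0, 1.30),
    ("pool6", "HoherSonnblick", "F_exsecta", 5.2, 0.87),
]

_CONGENERS = ["PCB28", "PCB52", "PCB101", "PCB138", "PCB153", "PCB180"]
_CONGENER_WEIGHTS = np.array([0.08, 0.12, 0.15, 0.25, 0.27, 0.13])


def default_burdens() -> pd.DataFrame:
    """Long-format pooled burden table (pool_id, location, taxon, analyte, conc)."""
    rows = []
    for pool_no, (pool_id, location, taxon, hg, sum_pcb) in enumerate(_POOLS):
        rows.append(
            {"pool_id": pool_id, "location": location, "taxon": taxon,
             "analyte": "Hg", "conc_ugkg_fw": hg}
        )
        # deterministic per-pool congener-profile variation so the seven
        # analytes are not mutually collinear across >2 pools
        jitter = 1.0 + 0.25 * np.sin(np.arange(len(_CONGENERS)) + pool_no)
        weights = _CONGENER_WEIGHTS * jitter
        weights = weights / weights.sum()
        for congener, w in zip(_CONGENERS, weights):
            rows.append(
                {"pool_id": pool_id, "location": location, "taxon": taxon,
                 "analyte": congener, "conc_ugkg_fw": round(w * sum_pcb, 4)}
            )
        rows.append(
            {"pool_id": pool_id, "location": location, "taxon": taxon,
             "analyte": "sumPCB", "conc_ugkg_fw": sum_pcb}
        )
    return pd.DataFrame(rows)


@dataclass
class StudyBundle:
    """In-memory synthetic study mirroring the published sampling layout."""

    forewings: LandmarkDataset
    hindwings: LandmarkDataset
    heads: dict  # species -> LandmarkDataset (object symmetry)
    genotypes_bees: GenotypeTable
    genotypes_ants: GenotypeTable
    burdens: pd.DataFrame
    membership: pd.DataFrame  # individual, pool_id, taxon
    error_study: dict  # structure -> LandmarkDataset with replication
    truth: dict


def _pool_fa_factors(membership: pd.DataFrame, burdens: pd.DataFrame, coupling: float):
    """Per-pool FA-scale multipliers proportional to the summed PCB burden."""
    sums = burdens[burdens["analyte"] == "sumPCB"].set_index("pool_id")["conc_ugkg_fw"]
    z = (sums - sums.min()) / max(sums.max() - sums.min(), 1e-12)
    return (1.0 + coupling * z).to_dict()


def make_study(
    seed: int,
    n_bees: tuple = (64, 4),
    n_aquilonia: tuple = (67, 48),
    n_exsecta: tuple = (49, 40),
    nests_aquilonia: tuple = (7, 5),
    nests_exsecta: tuple = (5, 4),
    burden_fa_coupling: float = 0.0,
    inbreeding_f: float = 0.05,
    out_dir=None,
    n_error_bees: int = 20,
    n_error_ants: int = 40,
    **landmark_overrides,
) -> StudyBundle:
    """Generate a complete study shaped like the published sampling design.

    Bumblebees (two locations, pooled per location) carry fore- and
    hindwing matching-symmetry datasets with 20 and 6 landmarks; the
    two ant species (pooled per species and location, individuals
    spread over nests) carry 29-landmark object-symmetry head
    datasets.  ``burden_fa_coupling`` > 0 scales each pool's FA
    variance with its summed PCB burden (positive control); 0 leaves
    FA independent of burden (null).  When ``out_dir`` is given, TPS
    and CSV files are also written there and round-trip through the
    readers.
    """
    burdens = default_burdens()
    locations = ["Zugspitze", "HoherSonnblick"]

    membership_rows = []
    bee_counts = dict(zip(locations, n_bees))
    for loc, count in bee_counts.items():
        pool = "pool1" if loc == "Zugspitze" else "pool4"
        offset = 0 if loc == "Zugspitze" else n_bees[0]
        for i in range(count):
            membership_rows.append(
                {"individual": f"bee{offset + i + 1:03d}", "pool_id": pool, "taxon": "Bombus"}
            )
    ant_layout = {
        "F_aquilonia": (n_aquilonia, nests_aquilonia, ("pool2", "pool5"), "aq"),
        "F_exsecta": (n_exsecta, nests_exsecta, ("pool3", "pool6"), "ex"),
    }
    for species, (counts, _nests, pools, prefix) in ant_layout.items():
        offset = 0
        for loc, count, pool in zip(locations, counts, pools):
            for i in range(count):
                membership_rows.append(
                    {"individual": f"{prefix}{offset + i + 1:03d}", "pool_id": pool, "taxon": species}
                )
            offset += count
    membership = pd.DataFrame(membership_rows)
    factors = _pool_fa_factors(membership, burdens, burden_fa_coupling)

    # --- bumblebee wings (matching symmetry) -------------------------------
    def bee_config(k, mean_size, seed_offset):
        return SyntheticConfig(
            seed=(seed + seed_offset) % 2**31,
            n_individuals=sum(n_bees),
            k=k,
            symmetry_mode="matching",
            mean_size=mean_size,
            species="Bombus_lucorum_complex",
            id_prefix="bee",
            inbreeding_f=inbreeding_f,
            **landmark_overrides,
        )

    bee_pool = ["pool1"] * n_bees[0] + ["pool4"] * n_bees[1]
    bee_factors = {i: factors[p] for i, p in enumerate(bee_pool)}
    forewings = make_landmarks(bee_config(20, 12.0, 11), per_individual_fa_scale=bee_factors)
    hindwings = make_landmarks(bee_config(6, 8.0, 12), per_individual_fa_scale=bee_factors)
    bee_locs = [locations[0]] * n_bees[0] + [locations[1]] * n_bees[1]
    for ds in (forewings, hindwings):
        for c in ds.configs:
            idx = int(c.classifiers["individual"][3:]) - 1
            c.classifiers["location"] = bee_locs[idx]

    # --- ant heads (object symmetry), one dataset per species -------------
    pairs, midline = default_pairing(13, 3)
    heads = {}
    ant_nest_of = {}
    for s_off, (species, (counts, nests, pools, prefix)) in enumerate(ant_layout.items()):
        cfg = SyntheticConfig(
            seed=(seed + 21 + s_off) % 2**31,
            n_individuals=sum(counts),
            k=29,
            symmetry_mode="object",
            pairing=pairs,
            midline=midline,
            mean_size=1.8,
            species=species,
            id_prefix=prefix,
            inbreeding_f=inbreeding_f,
            **landmark_overrides,
        )
        ant_pool = [pools[0]] * counts[0] + [pools[1]] * counts[1]
        ant_factors = {i: factors[p] for i, p in enumerate(ant_pool)}
        ds = make_landmarks(cfg, per_individual_fa_scale=ant_factors)
        ant_locs = [locations[0]] * counts[0] + [locations[1]] * counts[1]
        nest_names = []
        for loc, count, n_nest in zip(locations, counts, nests):
            nest_names += [f"{prefix}_{loc[:3]}_n{(i % n_nest) + 1}" for i in range(count)]
        for c in ds.configs:
            idx = int(c.classifiers["individual"][len(prefix):]) - 1
            c.classifiers["location"] = ant_locs[idx]
            c.classifiers["nest"] = nest_names[idx]
            ant_nest_of[c.classifiers["individual"]] = nest_names[idx]
        heads[species] = ds

    # --- error-study datasets with replicated imaging and digitizing -------
    error_study = {
        "forewings": make_landmarks(
            replace(
                bee_config(20, 12.0, 31),
                n_individuals=n_error_bees,
                n_image_rep=2,
                n_digit_rep=2,
                id_prefix="ebee",
            )
        ),
        "heads": make_landmarks(
            SyntheticConfig(
                seed=(seed + 32) % 2**31,
                n_individuals=n_error_ants,
                k=29,
                symmetry_mode="object",
                pairing=pairs,
                midline=midline,
                mean_size=1.8,
                species="F_aquilonia",
                id_prefix="eant",
                n_image_rep=2,
                n_digit_rep=2,
                **landmark_overrides,
            )
        ),
    }

    # --- genotypes ---------------------------------------------------------
    bee_ids = [f"bee{i + 1:03d}" for i in range(sum(n_bees))]
    genotypes_bees = make_genotypes(
        replace(bee_config(20, 12.0, 41), n_loci=7),
        ids=bee_ids,
        groups=pd.DataFrame({"species": "Bombus_lucorum_complex", "location": bee_locs}),
    )
    ant_ids, ant_species, ant_locs_all = [], [], []
    for species, (counts, _n, _p, prefix) in ant_layout.items():
        for i in range(sum(counts)):
            ant_ids.append(f"{prefix}{i + 1:03d}")
            ant_species.append(species)
        ant_locs_all += [locations[0]] * counts[0] + [locations[1]] * counts[1]
    genotypes_ants = make_genotypes(
        SyntheticConfig(seed=(seed + 42) % 2**31, n_individuals=len(ant_ids),
                        inbreeding_f=inbreeding_f, n_loci=13),
        ids=ant_ids,
        groups=pd.DataFrame(
            {"species": ant_species, "location": ant_locs_all,
             "nest": [ant_nest_of[i] for i in ant_ids]}
        ),
    )

    bundle = StudyBundle(
        forewings=forewings,
        hindwings=hindwings,
        heads=heads,
        genotypes_bees=genotypes_bees,
        genotypes_ants=genotypes_ants,
        burdens=burdens,
        membership=membership,
        error_study=error_study,
        truth={
            "seed": seed,
            "burden_fa_coupling": burden_fa_coupling,
            "inbreeding_f": inbreeding_f,
            "pool_fa_factors": factors,
        },
    )
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _write_bundle(bundle: StudyBundle, out_dir):
    os.makedirs(out_dir, exist_ok=True)

    def path(name):
        return os.path.join(out_dir, name)

    write_tps(bundle.forewings, path("forewings.tps"))
    write_tps(bundle.hindwings, path("hindwings.tps"))
    for species, ds in bundle.heads.items():
        write_tps(ds, path(f"heads_{species}.tps"))
    for name, ds in bundle.error_study.items():
        write_tps(ds, path(f"error_study_{name}.tps"))
    bundle.genotypes_bees.to_csv(path("genotypes_bees.csv"))
    bundle.genotypes_ants.to_csv(path("genotypes_ants.csv"))
    bundle.burdens.to_csv(path("burdens.csv"), index=False)
    bundle.membership.to_csv(path("membership.csv"), index=False)
    import yaml

    pairs, midline = bundle.heads[next(iter(bundle.heads))].pairing, bundle.heads[
        next(iter(bundle.heads))
    ].midline
    with open(path("head_pairing.yaml"), "w") as fh:
        yaml.safe_dump({"pairs": [list(p) for p in pairs], "midline": list(midline)}, fh)
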