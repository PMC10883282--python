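"""Synthetic study generator with machine-readable planted truth.

Emulates the full data footprint of a cell-line panel study — baseline
proteome and phosphoproteome intensity matrices, kinase/activation-loop/
substrate/periodic-cluster annotations, a multi-dose viability screen, and
a two-arm treatment time course — with a :class:`PlantedTruth` record so
every downstream stage has a recovery test.

The generative model:

* log10 intensities are Gaussian around a per-feature baseline
  (``noise_sd_log10`` across cell lines), missing uniformly at random;
* each cell line carries planted *active kinases*: the kinase's protein
  abundance, its own p-sites, its activation-loop sites and its substrate
  sites are all shifted up by ``kinase_effect_log10`` in that line;
* drugs annotated to a kinase that is active in a line have their true
  ED50 lowered ``sensitization_fold``-fold there — elevated activity causes
  sensitivity. A zero activity effect therefore produces a full null panel
  (no abundance shifts and no sensitisation);
* screen signals are drawn from the true 4PL curve between the plate's
  control levels, with Gaussian noise of ``viability_noise_frac`` times the
  negative-control mean (matching the low plate-to-plate variability of a
  well-run ATP assay);
* periodic-protein clusters get a per-line boost in that line's planted
  dominant cell-cycle cluster;
* marker links inject linear feature-abundance vs drug-AUC relationships;
* one vehicle-class drug is "cycle-coupled": sensitive exactly in the lines
  whose dominant cluster is S phase, giving the cluster-2 proportion a
  strongly negative AUC correlation.

One global seed fans out to per-table child seeds (numpy SeedSequence), so
regenerating one table never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dose_response import CurveFit, DrugResponseMatrix, four_pl, response_from_curves
from .io_formats import AnnotationSet, ScreenWellRecord, make_site_id
from .preprocessing import LINEAR, AbundanceMatrix

#: default 10-point 1:3 dilution ladder of final assay concentrations (µM):
#: a 10 mM top stock diluted 1:3 nine times, 2.5 µl dosed into 50 µl wells.
DEFAULT_DOSES_UM = tuple(10000.0 / 21.0 / 3.0**i for i in range(10))

TIMECOURSE_GRID_MIN = (0, 5, 10, 15, 30, 90, 180, 360, 720, 1440)
#: TMT channel -> minutes; channel 2 is the duplicated t0 bridge sample
TIMECOURSE_CHANNEL_MAP = {1: 0, 3: 5, 4: 10, 5: 15, 6: 30, 7: 90, 8: 180,
                          9: 360, 10: 720, 11: 1440}
BRIDGE_CHANNEL = 2


@dataclass
class PanelConfig:
    n_cell_lines: int = 17
    n_proteins: int = 2000
    n_psites: int = 4000
    n_kinases: int = 60
    n_drugs: int = 30
    doses: tuple[float, ...] = DEFAULT_DOSES_UM  # µM
    missing_rate: float = 0.1
    noise_sd_log10: float = 0.25
    seed: int = 0
    # planted-effect knobs
    kinase_effect_log10: float = 0.7
    sensitization_fold: float = 100.0
    active_kinases_per_line: int = 1
    sites_per_kinase: int = 3  # own p-sites; the first doubles as the loop site
    substrates_per_kinase: int = 5
    n_kinase_inhibitors: int = 24
    n_marker_links: int = 5
    marker_link_strength: float = 1.0  # log10 units per SD of AUC
    n_periodic_proteins: int = 119
    periodic_boost_log10: float = 0.5
    # screen plate layout
    n_replicates: int = 3
    n_control_wells: int = 16
    viability_noise_frac: float = 0.02  # SD as fraction of negative-control mean
    neg_control_mean: float = 1.0e5
    pos_control_mean: float = 2.0e3
    # time course
    n_timecourse_features: int = 1000
    timecourse_regulated_fraction: float = 0.1
    timecourse_noise_sd_log2: float = 0.1

    def __post_init__(self) -> None:
        for name in ("n_cell_lines", "n_proteins", "n_psites", "n_kinases",
                     "n_drugs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.n_kinases > self.n_proteins:
            raise ValueError("n_kinases cannot exceed n_proteins")
        if self.n_kinase_inhibitors > self.n_drugs:
            raise ValueError("n_kinase_inhibitors cannot exceed n_drugs")


@dataclass
class PlantedTruth:
    active_kinases: dict[str, set[str]]  # cell line -> elevated kinases
    drug_targets: dict[str, set[str]]  # drug -> target kinases
    kinase_inhibitors: set[str]
    true_curves: dict[tuple[str, str], tuple[float, float, float, float]]
    # (drug, line) -> (b, c, d, e)
    marker_links: list[tuple[str, str, int]]  # (feature, drug, slope sign)
    periodic_profile: dict[str, int]  # cell line -> dominant cluster
    cycle_drug: str | None = None
    regulated_features_timecourse: dict[str, tuple[str, float]] = field(
        default_factory=dict
    )  # feature -> (direction, plateau fold change on the ratio scale)

    def response_matrix(
        self, dose_range: tuple[float, float]
    ) -> DrugResponseMatrix:
        """Noise-free drug-response summaries implied by the true curves."""
        fits = {
            key: CurveFit(b=b, c=c, d=d, e=e, converged=True, rmse=0.0)
            for key, (b, c, d, e) in self.true_curves.items()
        }
        return response_from_curves(fits, dose_range)

    def to_json(self) -> str:
        payload = {
            "active_kinases": {k: sorted(v) for k, v in self.active_kinases.items()},
            "drug_targets": {k: sorted(v) for k, v in self.drug_targets.items()},
            "kinase_inhibitors": sorted(self.kinase_inhibitors),
            "true_curves": {
                f"{d}|{l}": list(params) for (d, l), params in self.true_curves.items()
            },
            "marker_links": [list(t) for t in self.marker_links],
            "periodic_profile": self.periodic_profile,
            "cycle_drug": self.cycle_drug,
            "regulated_features_timecourse": {
                k: list(v) for k, v in self.regulated_features_timecourse.items()
            },
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        raw = json.loads(text)
        return cls(
            active_kinases={k: set(v) for k, v in raw["active_kinases"].items()},
            drug_targets={k: set(v) for k, v in raw["drug_targets"].items()},
            kinase_inhibitors=set(raw["kinase_inhibitors"]),
            true_curves={
                (k.split("|")[0], k.split("|")[1]): tuple(v)
                for k, v in raw["true_curves"].items()
            },
            marker_links=[tuple(t) for t in raw["marker_links"]],
            periodic_profile={k: int(v) for k, v in raw["periodic_profile"].items()},
            cycle_drug=raw.get("cycle_drug"),
            regulated_features_timecourse={
                k: (v[0], float(v[1]))
                for k, v in raw["regulated_features_timecourse"].items()
            },
        )


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _ids(prefix: str, n: int, width: int = 4) -> list[str]:
    return [f"{prefix}{i + 1:0{width}d}" for i in range(n)]


def generate_panel(
    config: PanelConfig,
) -> tuple[AbundanceMatrix, AbundanceMatrix, AnnotationSet,
           list[ScreenWellRecord], PlantedTruth]:
    """Generate one full synthetic panel. Deterministic under the seed."""
    rng_design, rng_prot, rng_phos, rng_curves, rng_screen, _ = _child_rngs(
        config.seed, 6
    )
    lines = _ids("L", config.n_cell_lines, width=2)
    kinases = _ids("KIN", config.n_kinases, width=2)
    other_proteins = _ids("PR", config.n_proteins - config.n_kinases)
    proteins = kinases + other_proteins
    drugs = _ids("DRUG", config.n_drugs, width=2)

    # ---- p-site layout ----------------------------------------------------
    residues = ("S", "T", "Y")
    kinase_sites: dict[str, list[str]] = {}
    site_ids: list[str] = []
    for kin in kinases:
        own = [
            make_site_id(kin, residues[j % 3], 10 * (j + 1) + 3)
            for j in range(config.sites_per_kinase)
        ]
        kinase_sites[kin] = own
        site_ids.extend(own)
    n_other_sites = config.n_psites - len(site_ids)
    if n_other_sites < config.n_kinases * config.substrates_per_kinase:
        raise ValueError("n_psites too small for the substrate annotation")
    other_sites = []
    for j in range(n_other_sites):
        prot = other_proteins[j % len(other_proteins)]
        other_sites.append(
            make_site_id(prot, residues[j % 3], 7 * (j // len(other_proteins)) + 5)
        )
    site_ids.extend(other_sites)

    # substrate sets: disjoint chunks of non-kinase sites
    shuffled = list(other_sites)
    rng_design.shuffle(shuffled)
    substrate_sites = {
        kin: set(shuffled[i * config.substrates_per_kinase:
                          (i + 1) * config.substrates_per_kinase])
        for i, kin in enumerate(kinases)
    }
    loop_sites = {kin: {kinase_sites[kin][0]} for kin in kinases}

    # periodic clusters over non-kinase proteins
    n_per = config.n_periodic_proteins
    periodic_members = other_proteins[:n_per]
    cluster_of: dict[str, int] = {}
    periodic_clusters: dict[int, set[str]] = {c: set() for c in range(1, 6)}
    for i, prot in enumerate(periodic_members):
        label = i % 5 + 1
        periodic_clusters[label].add(prot)
        cluster_of[prot] = label
    periodic_profile = {line: i % 5 + 1 for i, line in enumerate(lines)}

    # ---- planted activity and drug targets --------------------------------
    active_kinases: dict[str, set[str]] = {}
    pool = list(kinases)
    rng_design.shuffle(pool)
    cursor = 0
    for line in lines:
        chosen = set()
        for _ in range(config.active_kinases_per_line):
            if cursor >= len(pool):
                rng_design.shuffle(pool)
                cursor = 0
            chosen.add(pool[cursor])
            cursor += 1
        active_kinases[line] = chosen

    planted = sorted({k for ks in active_kinases.values() for k in ks})
    ki_drugs = drugs[: config.n_kinase_inhibitors]
    drug_targets: dict[str, set[str]] = {d: set() for d in drugs}
    for i, drug in enumerate(ki_drugs):
        if i < len(planted):
            drug_targets[drug] = {planted[i]}
        else:
            drug_targets[drug] = {kinases[int(rng_design.integers(len(kinases)))]}
    cycle_drug = drugs[-1] if config.n_kinase_inhibitors < config.n_drugs else None

    # ---- true dose-response curves ----------------------------------------
    effect_on = config.kinase_effect_log10 > 0
    true_curves: dict[tuple[str, str], tuple[float, float, float, float]] = {}
    for drug in drugs:
        for line in lines:
            b = float(rng_curves.uniform(0.8, 1.5))
            c = float(rng_curves.uniform(0.0, 0.1))
            d = 1.0
            e = float(10 ** rng_curves.uniform(np.log10(2.0), np.log10(200.0)))
            if effect_on and drug_targets[drug] & active_kinases[line]:
                e /= config.sensitization_fold
            if drug == cycle_drug:
                e = 0.3 if periodic_profile[line] == 2 else 200.0
            true_curves[(drug, line)] = (b, c, d, e)

    # ---- intensity matrices ------------------------------------------------
    def build_matrix(ids: list[str], rng: np.random.Generator,
                     base_mean: float) -> pd.DataFrame:
        base = rng.normal(base_mean, 0.8, size=len(ids))
        vals = base[:, None] + rng.normal(
            0.0, config.noise_sd_log10, size=(len(ids), len(lines))
        )
        return pd.DataFrame(vals, index=ids, columns=lines)

    prot_log = build_matrix(proteins, rng_prot, 6.5)
    phos_log = build_matrix(site_ids, rng_phos, 5.5)

    # periodic proteins get a narrower abundance band: the phase signature is
    # carried by the whole cluster sum, which a single very abundant member
    # would otherwise dominate with its own sampling noise
    periodic_base = rng_prot.normal(6.0, 0.35, size=len(periodic_members))
    for prot, b in zip(periodic_members, periodic_base):
        prot_log.loc[prot, :] = b + rng_prot.normal(
            0.0, config.noise_sd_log10, size=len(lines)
        )

    if effect_on:
        for line, kins in active_kinases.items():
            for kin in kins:
                prot_log.loc[kin, line] += config.kinase_effect_log10
                shifted = (
                    kinase_sites[kin]
                    + sorted(loop_sites[kin] | substrate_sites[kin])
                )
                phos_log.loc[sorted(set(shifted)), line] += config.kinase_effect_log10
    for line, label in periodic_profile.items():
        prot_log.loc[sorted(periodic_clusters[label]), line] += (
            config.periodic_boost_log10
        )

    # marker links: features linearly tied to a drug's true AUC profile
    dose_range = (min(config.doses), max(config.doses))
    truth = PlantedTruth(
        active_kinases=active_kinases,
        drug_targets=drug_targets,
        kinase_inhibitors=set(ki_drugs),
        true_curves=true_curves,
        marker_links=[],
        periodic_profile=periodic_profile,
        cycle_drug=cycle_drug,
    )
    if config.n_marker_links > 0:
        true_resp = truth.response_matrix(dose_range)
        reserved = set(periodic_members) | set(kinases)
        candidates = [p for p in other_proteins if p not in reserved]
        planted_set = set(planted)
        link_drugs = [d for d in ki_drugs if drug_targets[d] & planted_set]
        for i in range(config.n_marker_links):
            feature = candidates[-(i + 1)]
            drug = link_drugs[i % len(link_drugs)]
            sign = 1 if i % 2 else -1  # negative: higher abundance, lower AUC
            auc = true_resp.auc.loc[drug, lines].to_numpy()
            sd = auc.std()
            if sd > 0:
                z = (auc - auc.mean()) / sd
                prot_log.loc[feature, :] = (
                    prot_log.loc[feature, :].mean()
                    + sign * config.marker_link_strength * z
                    + rng_design.normal(0, 0.1, size=len(lines))
                )
                truth.marker_links.append((feature, drug, sign))

    # missingness, uniform at random
    if config.missing_rate > 0:
        for df, rng in ((prot_log, rng_prot), (phos_log, rng_phos)):
            mask = rng.random(df.shape) < config.missing_rate
            df.mask(pd.DataFrame(mask, index=df.index, columns=df.columns),
                    inplace=True)

    proteome = AbundanceMatrix((10.0 ** prot_log), LINEAR)
    phospho = AbundanceMatrix((10.0 ** phos_log), LINEAR)

    annotations = AnnotationSet(
        kinase_ids=set(kinases),
        activation_loop_sites=loop_sites,
        substrate_sites=substrate_sites,
        druggable_kinases={k for d in ki_drugs for k in drug_targets[d]},
        periodic_clusters=periodic_clusters,
    )
    screen = _generate_screen(config, lines, drugs, true_curves, rng_screen)
    return proteome, phospho, annotations, screen, truth


def _generate_screen(
    config: PanelConfig,
    lines: list[str],
    drugs: list[str],
    true_curves: dict[tuple[str, str], tuple[float, float, float, float]],
    rng: np.random.Generator,
) -> list[ScreenWellRecord]:
    """One plate per cell line: all drugs at all doses plus control wells."""
    neg, pos = config.neg_control_mean, config.pos_control_mean
    sd = config.viability_noise_frac * neg
    records: list[ScreenWellRecord] = []

    def noisy(value: float) -> float:
        return float(value + rng.normal(0.0, sd)) if sd > 0 else float(value)

    for line in lines:
        for rep in range(1, config.n_replicates + 1):
            for i in range(config.n_control_wells):
                records.append(ScreenWellRecord(
                    drug="DMSO", cell_line=line, dose=0.0, replicate=rep,
                    signal=noisy(neg), well_role="negative_control"))
                records.append(ScreenWellRecord(
                    drug="STAUROSPORINE_LIKE", cell_line=line, dose=5.0,
                    replicate=rep, signal=noisy(pos),
                    well_role="positive_control"))
        for drug in drugs:
            b, c, d, e = true_curves[(drug, line)]
            for dose in config.doses:
                f = float(four_pl(dose, b, c, d, e))
                for rep in range(1, config.n_replicates + 1):
                    records.append(ScreenWellRecord(
                        drug=drug, cell_line=line, dose=float(dose),
                        replicate=rep, signal=noisy(pos + f * (neg - pos)),
                        well_role="sample"))
    return records


def generate_timecourse(
    config: PanelConfig, truth: PlantedTruth
) -> tuple[dict[str, pd.DataFrame], dict[int, int]]:
    """Two-arm (treated / vehicle) reporter-intensity time course.

    Regulated features follow an exponential approach on the log2 scale to a
    planted plateau fold change in the treated arm only; the vehicle arm is
    flat up to noise. Returns ``{"treated": df, "vehicle": df}`` (features x
    TMT channels, channel 2 being the duplicated t0 bridge) plus the
    channel -> minutes map. Updates ``truth.regulated_features_timecourse``.
    """
    rng = _child_rngs(config.seed, 7)[-1]
    n = config.n_timecourse_features
    features = _ids("TC", n)
    n_reg = int(round(n * config.timecourse_regulated_fraction))
    reg_idx = rng.choice(n, size=n_reg, replace=False)
    plateau_log2 = np.zeros(n)
    tau = rng.uniform(20.0, 180.0, size=n)
    signs = rng.choice([-1.0, 1.0], size=n_reg)
    plateau_log2[reg_idx] = signs * rng.uniform(1.2, 3.0, size=n_reg)

    truth.regulated_features_timecourse = {
        features[i]: (
            "up" if plateau_log2[i] > 0 else "down",
            float(2.0 ** plateau_log2[i]),
        )
        for i in reg_idx
    }

    times = np.array(TIMECOURSE_GRID_MIN, dtype=float)
    base = 10.0 ** rng.uniform(4.0, 7.0, size=n)
    arms: dict[str, pd.DataFrame] = {}
    channels = [1, BRIDGE_CHANNEL] + [
        ch for ch in TIMECOURSE_CHANNEL_MAP if ch not in (1, BRIDGE_CHANNEL)
    ]
    minutes_of = dict(TIMECOURSE_CHANNEL_MAP)
    minutes_of[BRIDGE_CHANNEL] = 0
    for arm in ("treated", "vehicle"):
        data = {}
        for ch in channels:
            t = minutes_of[ch]
            if arm == "treated":
                log2_ratio = plateau_log2 * (1.0 - np.exp(-t / tau))
            else:
                log2_ratio = np.zeros(n)
            noise = (
                rng.normal(0.0, config.timecourse_noise_sd_log2, size=n)
                if t > 0 or ch == BRIDGE_CHANNEL
                else np.zeros(n)
            )
            data[ch] = base * 2.0 ** (log2_ratio + noise)
        arms[arm] = pd.DataFrame(data, index=features)
    return arms, dict(TIMECOURSE_CHANNEL_MAP)


def make_grouped_response(
    n_samples: int = 17,
    n_groups: int = 2,
    n_drugs_per_group: int = 6,
    n_marker_features_per_block: int = 10,
    n_noise_features_per_block: int = 40,
    n_blocks: int = 2,
    noise_sd: float = 0.1,
    strengths: tuple[float, ...] = (1.0, 0.8),
    seed: int = 0,
) -> tuple[list[np.ndarray], np.ndarray, dict]:
    """Toy multiblock instance with orthogonal planted drug/marker groups.

    Each group g has an orthonormal latent sample score; its drugs and its
    marker features (in every block) load on that latent plus Gaussian
    noise, with per-group signal ``strengths``. Remaining features are pure
    noise. Returns the predictor blocks, the response matrix and the planted
    group memberships (column indices).
    """
    rng = np.random.default_rng(seed)
    Z, _ = np.linalg.qr(rng.normal(size=(n_samples, n_groups)))
    Z *= np.sqrt(n_samples)  # unit-variance latents
    n_drugs = n_groups * n_drugs_per_group
    Y = rng.normal(0.0, noise_sd, size=(n_samples, n_drugs))
    drug_groups = []
    for g in range(n_groups):
        cols = list(range(g * n_drugs_per_group, (g + 1) * n_drugs_per_group))
        drug_groups.append(cols)
        Y[:, cols] += strengths[g] * Z[:, [g]]
    X_blocks, feature_groups = [], []
    n_feat = n_groups * n_marker_features_per_block + n_noise_features_per_block
    for _ in range(n_blocks):
        X = rng.normal(0.0, noise_sd, size=(n_samples, n_feat))
        block_groups = []
        for g in range(n_groups):
            cols = list(range(g * n_marker_features_per_block,
                              (g + 1) * n_marker_features_per_block))
            X[:, cols] += strengths[g] * Z[:, [g]]
            block_groups.append(cols)
        X_blocks.append(X)
        feature_groups.append(block_groups)
    return X_blocks, Y, {"drug_groups": drug_groups,
                         "feature_groups": feature_groups}

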