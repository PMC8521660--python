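"""Synthetic common-garden study generator with planted ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every stage can be exercised and validated without external
data.  The emulated design: *Arabidopsis* plants grown in an axenic soil
substitute inoculated with one of two divergent source communities (AG,
agricultural; FO, forest) or their sterile 0.22-um filtrates, replicated at
an open-air location and in sealed growth-chamber microboxes that admit
colonists only from the soil.  Samples cover source soils, soil substitutes,
rosettes, leaves without soil contact, and flowers, plus negative controls
and one mock-community sample.

Generative model, in brief:

1. Two correlated log-normal soil profiles (correlation set by
   ``1 - soil_divergence``) over the soil ASV pool; an independent log-normal
   aerial pool exists only at the outside location.
2. A ``reachable_fraction`` of soil ASVs can reach the phyllosphere; the
   others never appear outside soil samples.  Growth-chamber samples draw
   exclusively from reachable ASVs (plus trace contamination) - the sealed
   microbox constraint.
3. ``n_drivers`` reachable taxa share one flower-specific expected
   sub-profile in every flower sample of every treatment and location (the
   planted convergence).  Their baseline weight is ~4% of a flower's
   background community; multiplying by ``driver_flower_fold`` (default 50)
   lifts them to ~68% of flower reads, in line with soil-derived taxa
   dominating floral communities.  Growth-chamber filtrate flowers carry no
   drivers (no viable source community).
4. Per-sample read depths are log-uniform over ``depth_range`` and counts
   are multinomial draws from the expected profile (Dirichlet overdispersion
   available as a stress knob; growth-chamber filtrate samples always use a
   heavily overdispersed residual-DNA draw, making their clustering
   unstable).
5. Negative controls contain only the ``contamination_asvs`` (which also
   pollute every real sample at ~0.2% of reads); the mock sample holds its
   expected members plus low-level bleed reads (mean ``mock_bleed_mean``)
   on random other ASVs.

A fixed seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .tables import CountTable, SampleRecord, SampleSheet, TaxonomyRecord, RANKS


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_asvs: int = 1500
    n_replicates_per_cell: int = 5
    depth_range: tuple[int, int] = (1084, 25000)
    n_drivers: int = 12
    driver_flower_fold: float = 50.0
    soil_divergence: float = 0.7
    reachable_fraction: float = 0.3
    contamination_asvs: int = 5
    mock_bleed_mean: float = 2.5
    n_negative_controls: int = 6
    n_mock_members: int = 8
    overdispersion: float = 0.0
    # baseline weight of the driver block inside a flower's background
    # community; with fold f the driver read share becomes
    # f*b / (f*b + 1 - b), ~68% at the defaults
    driver_baseline_share: float = 0.04

    def __post_init__(self) -> None:
        if self.n_asvs < self.n_drivers + self.contamination_asvs + self.n_mock_members + 10:
            raise ValueError("n_asvs too small for the requested structure")
        if self.n_drivers < 0 or self.contamination_asvs < 0:
            raise ValueError("counts must be non-negative")
        if self.driver_flower_fold < 1:
            raise ValueError("driver_flower_fold must be >= 1")
        if not 0 <= self.soil_divergence <= 1:
            raise ValueError("soil_divergence must be in [0, 1]")
        if not 0 < self.reachable_fraction <= 1:
            raise ValueError("reachable_fraction must be in (0, 1]")
        if self.depth_range[0] < 1000 or self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth_range must satisfy 1000 <= min <= max")
        if self.mock_bleed_mean < 1:
            raise ValueError("mock_bleed_mean must be >= 1")
        if not 0 < self.driver_baseline_share < 0.5:
            raise ValueError("driver_baseline_share must be in (0, 0.5)")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted structure of one synthetic study."""

    driver_asvs: frozenset
    reachable_asvs: frozenset
    contamination_asvs: frozenset
    mock_member_asvs: frozenset
    expected_clusters: dict  # name -> frozenset of sample ids
    config: SimulationConfig

    def __post_init__(self) -> None:
        if not self.driver_asvs <= self.reachable_asvs:
            raise ValueError("drivers must be a subset of reachable ASVs")


def _lognormal_weights(rng: np.random.Generator, n: int, sigma: float) -> np.ndarray:
    w = np.exp(sigma * rng.standard_normal(n))
    return w / w.sum()


def _mix(parts: Sequence[tuple[float, np.ndarray]]) -> np.ndarray:
    """Convex combination of full-length profiles (renormalised)."""
    out = sum(w * p for w, p in parts)
    total = out.sum()
    if total <= 0:
        raise ValueError("degenerate expected profile")
    return out / total


def generate_study(
    config: SimulationConfig,
) -> tuple[CountTable, SampleSheet, list[TaxonomyRecord], SyntheticTruth]:
    """Generate the full synthetic study: counts, metadata, taxonomy, truth."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_asvs
    asv_ids = [f"ASV_{k:04d}" for k in range(1, n + 1)]
    order = rng.permutation(n)

    # --- partition the ASV pool ---------------------------------------
    k = 0
    contam_idx = order[k : k + config.contamination_asvs]
    k += config.contamination_asvs
    mock_idx = order[k : k + config.n_mock_members]
    k += config.n_mock_members
    remaining = order[k:]
    n_soil = int(round(len(remaining) * 2 / 3))
    soil_idx = np.sort(remaining[:n_soil])
    aerial_idx = np.sort(remaining[n_soil:])
    n_reach = max(config.n_drivers, int(round(config.reachable_fraction * n_soil)))

    # --- expected profiles (all length n, zero outside their support) --
    sigma = 1.5
    rho = 1.0 - config.soil_divergence
    z0 = rng.standard_normal(n_soil)
    z_ag = rho * z0 + np.sqrt(1 - rho**2) * rng.standard_normal(n_soil)
    z_fo = rho * z0 + np.sqrt(1 - rho**2) * rng.standard_normal(n_soil)

    def soil_profile(z: np.ndarray) -> np.ndarray:
        p = np.zeros(n)
        p[soil_idx] = np.exp(sigma * z)
        return p / p.sum()

    s_full = {"AG": soil_profile(z_ag), "FO": soil_profile(z_fo)}
    # reachability is abundance-biased: taxa plentiful in soil are the ones
    # most likely to reach plant surfaces, which is what makes the abundant
    # tail of phyllosphere communities predominantly soil-capable
    soil_mean_w = s_full["AG"][soil_idx] + s_full["FO"][soil_idx]
    reach_p = np.sqrt(soil_mean_w)
    reach_p /= reach_p.sum()
    reach_idx = np.sort(
        rng.choice(soil_idx, size=n_reach, replace=False, p=reach_p)
    )
    driver_idx = np.sort(rng.choice(reach_idx, size=config.n_drivers, replace=False))
    driver_set = set(driver_idx.tolist())
    # the aerial pool is more even than soil, so individual aerial taxa
    # rarely dominate a plant community
    aerial = np.zeros(n)
    aerial[aerial_idx] = np.exp(1.0 * rng.standard_normal(len(aerial_idx)))
    aerial /= aerial.sum()
    contam = np.zeros(n)
    contam[contam_idx] = np.exp(0.5 * rng.standard_normal(len(contam_idx)))
    contam /= contam.sum()
    mock_members = np.zeros(n)
    mock_members[mock_idx] = np.exp(0.8 * rng.standard_normal(len(mock_idx)))
    mock_members /= mock_members.sum()

    # shared flower-driver sub-profile (the planted convergence): nearly
    # even so every driver is individually well above the detection floor
    d_norm = np.zeros(n)
    d_norm[driver_idx] = np.exp(0.25 * rng.standard_normal(len(driver_idx)))
    d_norm /= d_norm.sum()
    # per-ASV leaf filtering factors, shared across treatments
    leaf_aff = np.exp(1.0 * rng.standard_normal(n))

    b = config.driver_baseline_share

    def with_driver_block(profile: np.ndarray, block: float) -> np.ndarray:
        """Replace the profile's driver entries by the shared sub-profile at
        the given total weight."""
        base = profile.copy()
        base[driver_idx] = 0.0
        total = base.sum()
        if total <= 0:
            raise ValueError("profile carries no non-driver mass")
        return (1.0 - block) * base / total + block * d_norm

    def restrict(profile: np.ndarray, idx: np.ndarray) -> np.ndarray:
        p = np.zeros(n)
        p[idx] = profile[idx]
        total = p.sum()
        if total <= 0:
            raise ValueError("empty restricted profile")
        return p / total

    s_reach = {
        tr: with_driver_block(restrict(s_full[tr], reach_idx), b)
        for tr in ("AG", "FO")
    }
    s_full = {tr: with_driver_block(s_full[tr], b) for tr in ("AG", "FO")}
    s_leaf = {
        tr: with_driver_block(
            restrict(s_full[tr] * leaf_aff, reach_idx), b
        )
        for tr in ("AG", "FO")
    }
    fold = config.driver_flower_fold
    flower_share = fold * b / (fold * b + 1.0 - b)

    def flower_profile(background: np.ndarray) -> np.ndarray:
        return with_driver_block(background, flower_share)

    profiles: dict[tuple, np.ndarray] = {}
    for tr in ("AG", "FO"):
        src = tr
        profiles[("source", tr, "soil_original")] = s_full[tr]
        # outside: soils and plants gain aerial input
        profiles[("outside", tr, "soil_substitute")] = _mix(
            [(0.9, s_full[tr]), (0.1, aerial)]
        )
        profiles[("outside", tr, "rosette")] = _mix(
            [(0.55, s_reach[tr]), (0.45, aerial)]
        )
        profiles[("outside", tr, "leaf_no_soil_contact")] = _mix(
            [(0.5, s_leaf[tr]), (0.5, aerial)]
        )
        profiles[("outside", tr, "flower")] = flower_profile(
            _mix([(0.7, s_reach[tr]), (0.3, aerial)])
        )
        # growth chamber: sealed, soil-only colonisation, reachable taxa only
        profiles[("growth_chamber", tr, "soil_substitute")] = s_reach[tr]
        profiles[("growth_chamber", tr, "rosette")] = s_reach[tr]
        profiles[("growth_chamber", tr, "leaf_no_soil_contact")] = s_leaf[tr]
        profiles[("growth_chamber", tr, "flower")] = flower_profile(s_reach[tr])
        # filtrates: no viable community; outside plants live on aerial taxa
        ftr = f"{tr}_filtrate"
        profiles[("outside", ftr, "soil_substitute")] = _mix(
            [(0.5, aerial), (0.5, s_full[src])]
        )
        profiles[("outside", ftr, "rosette")] = _mix(
            [(0.85, aerial), (0.15, s_reach[src])]
        )
        profiles[("outside", ftr, "leaf_no_soil_contact")] = _mix(
            [(0.9, aerial), (0.1, s_leaf[src])]
        )
        profiles[("outside", ftr, "flower")] = flower_profile(
            _mix([(0.9, aerial), (0.1, s_reach[src])]
        ))
        # growth-chamber filtrate: residual DNA only, drawn with heavy
        # overdispersion at sampling time (flagged by this sentinel)
        for hab in ("soil_substitute", "rosette", "leaf_no_soil_contact", "flower"):
            profiles[("growth_chamber", ftr, hab)] = s_reach[src]

    # --- sample manifest ----------------------------------------------
    records: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    loc_code = {"outside": "out", "growth_chamber": "gc", "source": "src"}
    hab_code = {
        "soil_original": "soilorig",
        "soil_substitute": "soil",
        "rosette": "ros",
        "leaf_no_soil_contact": "leaf",
        "flower": "flw",
    }
    stage_code = {"adult": "ad", "flowering": "fl", "not_applicable": "na"}

    def contaminate(profile: np.ndarray) -> np.ndarray:
        return _mix([(0.998, profile), (0.002, contam)])

    def draw_depth() -> int:
        lo, hi = config.depth_range
        return int(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    def draw_counts(profile: np.ndarray, depth: int, disp: float) -> np.ndarray:
        p = profile
        if disp > 0:
            support = p > 0
            alpha = p[support] / disp
            q = np.zeros(n)
            q[support] = rng.dirichlet(alpha)
            p = q
        return rng.multinomial(depth, p)

    def add_sample(
        sample_id: str,
        location: str,
        habitat: str,
        treatment: str,
        stage: str,
        profile: np.ndarray,
        depth: int,
        disp: float,
    ) -> None:
        records.append(
            SampleRecord(sample_id, location, habitat, treatment, stage)
        )
        rows.append(draw_counts(profile, depth, disp))

    n_rep = config.n_replicates_per_cell
    for tr in ("AG", "FO"):
        for r in range(1, n_rep + 1):
            add_sample(
                f"src_{tr}_soilorig_na_{r}",
                "source",
                "soil_original",
                tr,
                "not_applicable",
                contaminate(profiles[("source", tr, "soil_original")]),
                draw_depth(),
                config.overdispersion,
            )
    cells = []
    for loc in ("outside", "growth_chamber"):
        for tr in ("AG", "FO", "AG_filtrate", "FO_filtrate"):
            cells.append((loc, tr, "soil_substitute", "flowering"))
            cells.append((loc, tr, "rosette", "adult"))
            cells.append((loc, tr, "rosette", "flowering"))
            cells.append((loc, tr, "leaf_no_soil_contact", "flowering"))
            cells.append((loc, tr, "flower", "flowering"))
    for loc, tr, hab, stage in cells:
        profile = contaminate(profiles[(loc, tr, hab)])
        # residual-DNA draws in sealed filtrate boxes are wildly variable
        gc_filtrate = loc == "growth_chamber" and tr.endswith("_filtrate")
        disp = 0.2 if gc_filtrate else config.overdispersion
        # growth-chamber filtrate flowers carry no drivers: no viable source
        if gc_filtrate and hab == "flower":
            base = profile.copy()
            base[driver_idx] = 0.0
            profile = base / base.sum()
        tr_code = tr.replace("_filtrate", "f")
        for r in range(1, n_rep + 1):
            add_sample(
                f"{loc_code[loc]}_{tr_code}_{hab_code[hab]}_{stage_code[stage]}_{r}",
                loc,
                hab,
                tr,
                stage,
                profile,
                draw_depth(),
                disp,
            )
    # negative controls: contamination ASVs only, shallow
    for r in range(1, config.n_negative_controls + 1):
        records.append(
            SampleRecord(f"src_neg_ctrl_na_{r}", "source", "negative_control", "none", "not_applicable")
        )
        rows.append(rng.multinomial(int(rng.integers(300, 800)), contam))
    # mock community: expected members plus low-level bleed on random ASVs
    mock_counts = rng.multinomial(22_860, mock_members)
    non_member = np.setdiff1d(np.arange(n), mock_idx)
    bleed_at = rng.choice(non_member, size=40, replace=False)
    mock_counts[bleed_at] += 1 + rng.poisson(config.mock_bleed_mean - 1.0, size=40)
    records.append(
        SampleRecord("src_mock_ctrl_na_1", "source", "mock_control", "none", "not_applicable")
    )
    rows.append(mock_counts)

    table = CountTable.from_arrays(
        [r.sample_id for r in records], asv_ids, np.vstack(rows)
    )
    sheet = SampleSheet(records)

    # --- taxonomy ------------------------------------------------------
    burk_genera = (
        "Burkholderia-Caballeronia-Paraburkholderia",
        "Pandoraea",
        "Ralstonia",
    )
    taxonomy: list[TaxonomyRecord] = []
    driver_list = driver_idx.tolist()
    for j, asv in enumerate(asv_ids):
        if j in driver_set:
            genus = burk_genera[driver_list.index(j) % len(burk_genera)]
            lineage = (
                "Bacteria", "Proteobacteria", "Gammaproteobacteria",
                "Burkholderiales", "Burkholderiaceae", genus,
            )
        elif j in set(contam_idx.tolist()):
            lineage = (
                "Bacteria", "Proteobacteria", "Alphaproteobacteria",
                "Sphingomonadales", "Sphingomonadaceae", "Sphingomonas",
            )
        elif j in set(mock_idx.tolist()):
            lineage = (
                "Bacteria", "Firmicutes", "Bacilli",
                "Bacillales", "Bacillaceae", "Bacillus",
            )
        else:
            lineage = (
                "Bacteria", f"phylum_{j % 7}", f"class_{j % 13}",
                f"order_{j % 29}", f"family_{j % 53}", "",
            )
        taxonomy.append(TaxonomyRecord(asv, lineage, "reference_db"))

    # --- ground truth --------------------------------------------------
    def ids_at(idx: np.ndarray) -> frozenset:
        return frozenset(asv_ids[int(i)] for i in idx)

    outside_flowers = frozenset(
        sheet.select(location="outside", habitat="flower")
    )
    expected_clusters = {
        "floral_outside": outside_flowers,
        "rosette_outside_AG_flowering": frozenset(
            sheet.select(location="outside", habitat="rosette", treatment="AG", stage="flowering")
        ),
        "rosette_outside_FO_flowering": frozenset(
            sheet.select(location="outside", habitat="rosette", treatment="FO", stage="flowering")
        ),
        "soil_outside_AG": frozenset(
            sheet.select(location="outside", habitat="soil_substitute", treatment="AG")
        ),
        "soil_outside_FO": frozenset(
            sheet.select(location="outside", habitat="soil_substitute", treatment="FO")
        ),
        "soil_gc_AG": frozenset(
            sheet.select(location="growth_chamber", habitat="soil_substitute", treatment="AG")
        ),
        "soil_gc_FO": frozenset(
            sheet.select(location="growth_chamber", habitat="soil_substitute", treatment="FO")
        ),
        "source_AG": frozenset(sheet.select(location="source", treatment="AG")),
        "source_FO": frozenset(sheet.select(location="source", treatment="FO")),
    }
    truth = SyntheticTruth(
        driver_asvs=ids_at(driver_idx),
        reachable_asvs=ids_at(reach_idx),
        contamination_asvs=ids_at(contam_idx),
        mock_member_asvs=ids_at(mock_idx),
        expected_clusters=expected_clusters,
        config=config,
    )
    return table, sheet, taxonomy, truth


def truth_metrics(
    result,
    truth: SyntheticTruth,
    universe: Sequence[str] | None = None,
) -> tuple[float, float]:
    """Precision and recall of driver recovery against the planted truth.

    ``result`` may be a :class:`~phyllocom.drivers.DriverScreenResult` (its
    candidate list and ASV universe are used) or a plain candidate id
    collection.
    """
    if hasattr(result, "candidates") and hasattr(result, "per_asv_recovery"):
        if universe is None:
            universe = list(result.per_asv_recovery)
        result = result.candidates
    cand = set(result)
    drivers = set(truth.driver_asvs)
    if universe is not None:
        unknown = (cand | drivers) - set(universe)
        if unknown:
            raise ValueError(
                f"ASV id(s) outside the analysed universe: {sorted(unknown)[:5]}"
            )
    if not cand:
        precision = 1.0 if not drivers else 0.0
    else:
        precision = len(cand & drivers) / len(cand)
    recall = 1.0 if not drivers else len(cand & drivers) / len(drivers)
    return precision, recall
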