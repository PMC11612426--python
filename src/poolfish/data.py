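"""Survey data containers, IO, filtering and covariate scaling.

Multi-gear detection/non-detection surveys of fish in disconnected river
pools are held as five normalized tables (species, pools, visits, samples,
catch) plus a binary detection tensor.  Covariates live on two spatial
scales: the pool (mesohabitat, maximum depth, turbidity, structural
complexity, river kilometre, conductivity) and the individual gear sample
(depth, complexity, effort).  Depth-like covariates and effort are scaled
to a maximum of one (the Ricker abundance form requires depth in (0, 1]);
the remaining covariates and species mean length are centered to mean zero
and scaled to unit (population) standard deviation.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

GEARS = ("backpack_EF", "boat_EF", "seine_LM", "seine_SM")
EF_GEARS = ("backpack_EF", "boat_EF")
SEINE_VARIANTS = ("none", "seine5m", "seine10m")

SPECIES_COLUMNS = ["species_id", "mean_length"]
POOL_COLUMNS = ["pool_id", "mesohabitat", "max_depth", "turbidity",
                "complexity", "river_km", "conductivity"]
VISIT_COLUMNS = ["visit_id", "pool_id", "year"]
SAMPLE_COLUMNS = ["sample_id", "visit_id", "gear", "effort_raw",
                  "sample_depth", "sample_complexity", "seine_variant"]
CATCH_COLUMNS = ["species_id", "sample_id", "count"]

#: covariates standardized to mean 0 / SD 1 (population SD, ddof=0)
STANDARDIZED = ("turbidity", "complexity", "river_km", "conductivity",
                "sample_complexity", "length")


class SurveyDataError(ValueError):
    """Raised on malformed or referentially broken survey tables."""


@dataclass
class DetectionArray:
    """Binary detections indexed (species, visit, sample-within-visit).

    Sample counts differ between visits, so ``y`` is rectangular with a
    per-(visit, slot) validity ``mask``; invalid slots hold 0.
    """

    y: np.ndarray          # (n_species, n_visits, k_max) int8
    mask: np.ndarray       # (n_visits, k_max) bool

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.int8)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.y.ndim != 3 or self.mask.shape != self.y.shape[1:]:
            raise SurveyDataError("detection array / mask shape mismatch")
        valid = self.y[:, self.mask]
        if valid.size and not np.isin(valid, (0, 1)).all():
            raise SurveyDataError("non-binary detection value")

    @property
    def n_species(self) -> int:
        return self.y.shape[0]

    @property
    def n_visits(self) -> int:
        return self.y.shape[1]

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (y_flat of shape (n_species, n_samples), visit index per sample)."""
        vis, slot = np.nonzero(self.mask)
        return self.y[:, vis, slot], vis


@dataclass
class ScalingInfo:
    """Frozen scaling constants; reused verbatim for any later prediction."""

    depth_divisor: float
    sample_depth_divisor: float
    effort_divisor: dict[str, float]
    center: dict[str, float]
    sd: dict[str, float]

    def __post_init__(self) -> None:
        bad = [k for k, v in {"depth": self.depth_divisor,
                              "sample_depth": self.sample_depth_divisor,
                              **self.effort_divisor}.items() if not v > 0]
        if bad:
            raise SurveyDataError(f"nonpositive scaling divisor for {bad}")
        for k, s in self.sd.items():
            if not s > 0:
                raise SurveyDataError(f"zero-variance covariate {k!r}: cannot standardize")

    def standardize(self, name: str, x):
        return (np.asarray(x, float) - self.center[name]) / self.sd[name]

    def unstandardize(self, name: str, z):
        return np.asarray(z, float) * self.sd[name] + self.center[name]

    def scale_depth(self, d):
        return np.asarray(d, float) / self.depth_divisor


@dataclass
class SurveyDataset:
    """A validated multi-gear pool survey.

    Tables are pandas DataFrames with the documented columns; row order is
    the canonical index order used by the detection array and the model.
    """

    species: pd.DataFrame
    pools: pd.DataFrame
    visits: pd.DataFrame
    samples: pd.DataFrame
    detections: DetectionArray
    scaling: ScalingInfo | None = None
    truth: object | None = None        # TruthBundle from poolfish.synthetic

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def is_scaled(self) -> bool:
        return self.scaling is not None

    def samples_per_visit(self) -> np.ndarray:
        counts = self.samples["visit_id"].value_counts()
        return counts.reindex(self.visits["visit_id"], fill_value=0).to_numpy()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name, df, cols in (("species", self.species, SPECIES_COLUMNS),
                               ("pools", self.pools, POOL_COLUMNS),
                               ("visits", self.visits, VISIT_COLUMNS),
                               ("samples", self.samples, SAMPLE_COLUMNS)):
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise SurveyDataError(f"{name} table missing column(s) {missing}")
            if df[cols[0]].duplicated().any():
                raise SurveyDataError(f"duplicate {cols[0]} in {name} table")

        if not self.visits["pool_id"].isin(self.pools["pool_id"]).all():
            raise SurveyDataError("orphan reference: visit names unknown pool")
        if self.visits.duplicated(["pool_id", "year"]).any():
            raise SurveyDataError("duplicate (pool_id, year) visit")
        if not self.samples["visit_id"].isin(self.visits["visit_id"]).all():
            raise SurveyDataError("orphan reference: sample names unknown visit")
        if self.n_visits and (self.samples_per_visit() == 0).any():
            raise SurveyDataError("visit without any sample")

        if (self.species["mean_length"] <= 0).any():
            raise SurveyDataError("nonpositive species mean length")
        if not self.pools["mesohabitat"].isin((0, 1)).all():
            raise SurveyDataError("mesohabitat must be 0 (main channel) or 1 (floodplain)")
        if (self.pools["max_depth"] <= 0).any():
            raise SurveyDataError("nonpositive pool max depth")
        if (~self.pools["complexity"].between(0, 100)).any():
            raise SurveyDataError("pool complexity outside 0-100%")
        if (self.samples["effort_raw"] <= 0).any():
            raise SurveyDataError("nonpositive sampling effort")
        if (self.samples["sample_depth"] <= 0).any():
            raise SurveyDataError("nonpositive sample depth")
        if not self.samples["gear"].isin(GEARS).all():
            raise SurveyDataError(f"unknown gear; expected one of {GEARS}")
        is_lm = self.samples["gear"] == "seine_LM"
        has_var = self.samples["seine_variant"] != "none"
        if (is_lm ^ has_var).any():
            raise SurveyDataError("seine_variant must be set exactly for seine_LM samples")

        ef_pools = self.visits.set_index("visit_id").loc[
            self.samples.loc[self.samples["gear"].isin(EF_GEARS), "visit_id"], "pool_id"]
        cond = self.pools.set_index("pool_id")["conductivity"]
        if ef_pools.size and cond.reindex(ef_pools).isna().any():
            raise SurveyDataError("missing conductivity for pool with electrofishing samples")

        da = self.detections
        if da.y.shape != (self.n_species, self.n_visits, da.y.shape[2]):
            raise SurveyDataError("detection array does not match species/visit counts")
        if da.mask.sum() != self.n_samples:
            raise SurveyDataError("detection mask does not match sample count")
        spv = self.samples_per_visit()
        expect = np.arange(da.mask.shape[1])[None, :] < spv[:, None]
        if not np.array_equal(da.mask, expect):
            raise SurveyDataError("detection mask is not left-packed per visit")

        if self.is_scaled:
            for col, frame in (("depth_scaled", self.pools),
                               ("effort_scaled", self.samples),
                               ("sample_depth_scaled", self.samples)):
                if col not in frame.columns:
                    raise SurveyDataError(f"scaled dataset lacks column {col}")
                v = frame[col].to_numpy(float)
                if not ((v > 0) & (v <= 1 + 1e-12)).all():
                    raise SurveyDataError(f"{col} outside (0, 1]")


# ----------------------------------------------------------------------
# construction helpers

def build_detection_array(samples: pd.DataFrame, visits: pd.DataFrame,
                          species: pd.DataFrame,
                          detected: pd.DataFrame) -> DetectionArray:
    """Assemble the (species, visit, slot) tensor from a long detection table.

    ``detected`` has columns species_id, sample_id, value (0/1); absent
    pairs are non-detections.  Samples occupy slots in table order within
    their visit.
    """
    visit_pos = {v: i for i, v in enumerate(visits["visit_id"])}
    sp_pos = {s: i for i, s in enumerate(species["species_id"])}
    unknown = set(samples["visit_id"]) - set(visit_pos)
    if unknown:
        raise SurveyDataError(
            f"orphan reference: sample names unknown visit {sorted(unknown)}")
    vis_of_sample = samples["visit_id"].map(visit_pos).to_numpy()
    slot = np.zeros(len(samples), dtype=int)
    seen: dict[int, int] = {}
    for n, v in enumerate(vis_of_sample):
        slot[n] = seen.get(v, 0)
        seen[v] = slot[n] + 1
    k_max = int(slot.max()) + 1 if len(samples) else 1
    mask = np.zeros((len(visits), k_max), dtype=bool)
    mask[vis_of_sample, slot] = True
    y = np.zeros((len(species), len(visits), k_max), dtype=np.int8)

    if len(detected):
        unknown = set(detected["species_id"]) - set(sp_pos)
        if unknown:
            raise SurveyDataError(f"orphan reference: catch names unknown species {sorted(unknown)}")
        samp_pos = {s: i for i, s in enumerate(samples["sample_id"])}
        unknown = set(detected["sample_id"]) - set(samp_pos)
        if unknown:
            raise SurveyDataError(f"orphan reference: catch names unknown sample {sorted(unknown)}")
        si = detected["species_id"].map(sp_pos).to_numpy()
        ki = detected["sample_id"].map(samp_pos).to_numpy()
        y[si, vis_of_sample[ki], slot[ki]] = detected["value"].to_numpy()
    return DetectionArray(y=y, mask=mask)


def binarize_catch(counts: np.ndarray, mask: np.ndarray | None = None) -> DetectionArray:
    """Detection/non-detection indicator from a count tensor: y = 1[count >= 1]."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise SurveyDataError("negative catch count")
    if mask is None:
        mask = np.ones(counts.shape[1:], dtype=bool)
    y = (counts >= 1).astype(np.int8)
    y[:, ~np.asarray(mask, bool)] = 0
    return DetectionArray(y=y, mask=mask)


# ----------------------------------------------------------------------
# IO

_TABLE_FILES = {"species": "species.csv", "pools": "pools.csv",
                "visits": "visits.csv", "samples": "samples.csv"}


def load_survey(tables_path: str, config: dict | None = None) -> SurveyDataset:
    """Read the five delimited tables under ``tables_path`` and validate.

    catch.csv carries raw counts (columns species_id, sample_id, count);
    detections are the binarized counts.  ``config`` may override file
    names with keys species/pools/visits/samples/catch.
    """
    config = config or {}
    frames = {}
    for key, default in _TABLE_FILES.items():
        path = os.path.join(tables_path, config.get(key, default))
        if not os.path.exists(path):
            raise SurveyDataError(f"missing table file {path}")
        frames[key] = pd.read_csv(path)
    catch_path = os.path.join(tables_path, config.get("catch", "catch.csv"))
    if not os.path.exists(catch_path):
        raise SurveyDataError(f"missing table file {catch_path}")
    catch = pd.read_csv(catch_path)
    missing = [c for c in CATCH_COLUMNS if c not in catch.columns]
    if missing:
        raise SurveyDataError(f"catch table missing column(s) {missing}")
    if (catch["count"] < 0).any():
        raise SurveyDataError("negative catch count")

    samples = frames["samples"]
    if "seine_variant" not in samples.columns:
        samples["seine_variant"] = "none"
    samples["seine_variant"] = samples["seine_variant"].fillna("none")
    samples, pools_lookup = _impute_sample_complexity(samples, frames["visits"], frames["pools"])

    detected = catch.assign(value=(catch["count"] >= 1).astype(np.int8))
    da = build_detection_array(samples, frames["visits"], frames["species"], detected)
    return SurveyDataset(species=frames["species"], pools=frames["pools"],
                         visits=frames["visits"], samples=samples, detections=da)


def _impute_sample_complexity(samples, visits, pools):
    """Fill missing sample-scale complexity with the pool-scale value, flagged."""
    samples = samples.copy()
    miss = samples["sample_complexity"].isna()
    samples["complexity_imputed"] = miss
    if miss.any():
        pool_of_visit = visits.set_index("visit_id")["pool_id"]
        cplx = pools.set_index("pool_id")["complexity"]
        samples.loc[miss, "sample_complexity"] = (
            samples.loc[miss, "visit_id"].map(pool_of_visit).map(cplx).to_numpy())
    return samples, None


def write_survey(dataset: SurveyDataset, out_path: str) -> None:
    """Serialize as normalized CSVs (counts are written as the 0/1 detections)."""
    os.makedirs(out_path, exist_ok=True)
    dataset.species[SPECIES_COLUMNS].to_csv(os.path.join(out_path, "species.csv"), index=False)
    dataset.pools[POOL_COLUMNS].to_csv(os.path.join(out_path, "pools.csv"), index=False)
    dataset.visits[VISIT_COLUMNS].to_csv(os.path.join(out_path, "visits.csv"), index=False)
    cols = [c for c in SAMPLE_COLUMNS if c in dataset.samples.columns]
    dataset.samples[cols].to_csv(os.path.join(out_path, "samples.csv"), index=False)
    y_flat, vis = dataset.detections.flat()
    si, ki = np.nonzero(y_flat)
    catch = pd.DataFrame({
        "species_id": dataset.species["species_id"].to_numpy()[si],
        "sample_id": dataset.samples["sample_id"].to_numpy()[ki],
        "count": np.ones(len(si), dtype=int),
    })
    catch.to_csv(os.path.join(out_path, "catch.csv"), index=False)


# ----------------------------------------------------------------------
# filtering and scaling

def detection_events(dataset: SurveyDataset) -> np.ndarray:
    """Per species, the number of site-visits with at least one detection."""
    return (dataset.detections.y.any(axis=2)).sum(axis=1)


def filter_rare_species(dataset: SurveyDataset, min_events: int = 3
                        ) -> tuple[SurveyDataset, list[str]]:
    """Drop species detected at fewer than ``min_events`` site-visits.

    A detection event is a site-visit (pool x year) at which the species
    was caught in any sample by any gear.  The default of 3 removes species
    caught at two or fewer events.
    """
    if min_events < 1:
        raise ValueError("min_events must be >= 1")
    if dataset.n_species == 0:
        return dataset, []
    keep = detection_events(dataset) >= min_events
    removed = list(dataset.species.loc[~keep, "species_id"])
    if not removed:
        return dataset, []
    da = DetectionArray(y=dataset.detections.y[keep], mask=dataset.detections.mask)
    out = replace(dataset, species=dataset.species.loc[keep].reset_index(drop=True),
                  detections=da)
    return out, removed


def scale_covariates(dataset: SurveyDataset) -> SurveyDataset:
    """Populate scaled covariate columns and freeze the constants.

    Depth-like quantities and per-gear effort are divided by their maximum
    (so they lie in (0, 1]); turbidity, complexity (both scales), river km,
    conductivity and species mean length are standardized with the
    population SD.
    """
    pools = dataset.pools.copy()
    samples = dataset.samples.copy()
    species = dataset.species.copy()

    eff_div = {}
    eff_scaled = np.empty(len(samples))
    for g in GEARS:
        sel = (samples["gear"] == g).to_numpy()
        if sel.any():
            eff_div[g] = float(samples.loc[sel, "effort_raw"].max())
            eff_scaled[sel] = samples.loc[sel, "effort_raw"].to_numpy() / eff_div[g]
        else:
            eff_div[g] = 1.0

    center, sd = {}, {}

    def _standardize(name, values):
        v = np.asarray(values, float)
        center[name] = float(np.nanmean(v))
        sd[name] = float(np.nanstd(v))          # population SD, ddof=0
        if not sd[name] > 0:
            raise SurveyDataError(f"zero-variance covariate {name!r}: cannot standardize")
        return (v - center[name]) / sd[name]

    pools["turbidity_std"] = _standardize("turbidity", pools["turbidity"])
    pools["complexity_std"] = _standardize("complexity", pools["complexity"])
    pools["river_km_std"] = _standardize("river_km", pools["river_km"])
    pools["conductivity_std"] = _standardize("conductivity", pools["conductivity"])
    samples["sample_complexity_std"] = _standardize(
        "sample_complexity", samples["sample_complexity"])
    species["length_std"] = _standardize("length", species["mean_length"])

    info = ScalingInfo(
        depth_divisor=float(pools["max_depth"].max()),
        sample_depth_divisor=float(samples["sample_depth"].max()),
        effort_divisor=eff_div, center=center, sd=sd)
    pools["depth_scaled"] = pools["max_depth"] / info.depth_divisor
    samples["sample_depth_scaled"] = samples["sample_depth"] / info.sample_depth_divisor
    samples["effort_scaled"] = eff_scaled

    return replace(dataset, species=species, pools=pools, samples=samples, scaling=info)
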