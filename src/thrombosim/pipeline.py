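"""Serial treatment pipeline over section cohorts and pressure sweeps.

The stages run serially with no feedback, mirroring a staged therapy:
synthetic histology -> focal pressure map -> Monte Carlo ablation ->
steady rt-PA transport -> fibrinolysis totals -> statistics. Every stage
is reproducible from (config, master seed); each (section, pressure) cell
fails independently with a logged diagnostic rather than aborting the
whole sweep.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import histology, kinetics, montecarlo, transport
from .acoustics import SourceSpec, elliptical_gaussian_field
from .bubble import MaterialParameters
from .histology import HistologySection, Subgroup
from .kinetics import KineticParameters
from .montecarlo import NucleationModel
from .stats import linear_regression_coefficient
from .transport import PolarGrid, TransportParameters

__all__ = ["ExperimentConfig", "generate_cohort", "run_experiment", "summarize", "zlrc_by_section"]

log = logging.getLogger("thrombosim")

DEFAULT_PRESSURES_MPA = (0.0, 28.0, 30.0, 32.0, 34.0, 36.0, 38.0, 40.0)

# synthetic cohort composition ranges (fibrin fraction) per subgroup
_SUBGROUP_RANGES = {
    Subgroup.FIBRIN_DOMINANT: (0.80, 0.95),
    Subgroup.HALF_HALF: (0.30, 0.70),
    Subgroup.RBC_DOMINANT: (0.05, 0.20),
}


@dataclass
class ExperimentConfig:
    """Everything needed to rerun a full sweep deterministically."""

    n_fibrin_dominant: int = 7
    n_half_half: int = 8
    n_rbc_dominant: int = 7
    section_paths: tuple[str, ...] = ()  # overrides the generated cohort if set
    pressures_mpa: tuple[float, ...] = DEFAULT_PRESSURES_MPA
    n_pulses: int = 1000
    n_repeats: int = 10
    pixel_size_um: float = 7.4
    extent_mm: float = 10.0
    clustering_scale_mm: float = 0.5
    transport_dr_cm: float = 0.002
    transport_duration_s: float = 20.0
    seed: int = 0
    output_dir: str | None = None
    material: MaterialParameters = field(default_factory=MaterialParameters)
    nucleation: NucleationModel = field(default_factory=NucleationModel)
    transport_params: TransportParameters = field(default_factory=TransportParameters)
    kinetic_params: KineticParameters = field(default_factory=KineticParameters)

    def __post_init__(self) -> None:
        if len(self.pressures_mpa) == 0:
            raise ValueError("pressure sweep must be non-empty")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        nested = {
            "material": MaterialParameters,
            "nucleation": NucleationModel,
            "transport_params": TransportParameters,
            "kinetic_params": KineticParameters,
        }
        for k, v in raw.items():
            if k in nested:
                kwargs[k] = nested[k](**v)
            elif isinstance(v, list):
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for k in ("material", "nucleation", "transport_params", "kinetic_params"):
            d[k] = {kk: vv for kk, vv in d[k].items() if not callable(vv)}
        d["pressures_mpa"] = list(self.pressures_mpa)
        d["section_paths"] = list(self.section_paths)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def generate_cohort(config: ExperimentConfig) -> list[tuple[str, HistologySection]]:
    """Synthetic cohort with per-subgroup composition draws.

    Target fibrin fractions are drawn uniformly within each subgroup's
    range from a stream derived from the master seed; section seeds are
    derived the same way, so the cohort is reproducible.
    """
    if config.section_paths:
        return [(Path(p).stem, histology.read_label_mask(p)) for p in config.section_paths]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xC040]))
    out: list[tuple[str, HistologySection]] = []
    plan = [
        (Subgroup.FIBRIN_DOMINANT, config.n_fibrin_dominant),
        (Subgroup.HALF_HALF, config.n_half_half),
        (Subgroup.RBC_DOMINANT, config.n_rbc_dominant),
    ]
    for subgroup, count in plan:
        lo, hi = _SUBGROUP_RANGES[subgroup]
        for i in range(count):
            target = float(rng.uniform(lo, hi))
            sec_seed = int(rng.integers(0, 2**31 - 1))
            sec = histology.generate_section(
                target_fibrin_fraction=target,
                clustering_scale_mm=config.clustering_scale_mm,
                extent_mm=config.extent_mm,
                pixel_size_um=config.pixel_size_um,
                seed=sec_seed,
            )
            out.append((f"{subgroup.value}_{i:02d}", sec))
    return out


def _treat_cell(section: HistologySection, pressure_mpa: float,
                config: ExperimentConfig, cell_seed: int):
    """Monte Carlo + transport + fibrinolysis for one (section, pressure)."""
    if pressure_mpa > 0:
        spec = SourceSpec(peak_negative_pressure_mpa=pressure_mpa)
        pfield = elliptical_gaussian_field(spec, section)
        result = montecarlo.run_treatment(
            section, pfield, config.material, config.nucleation,
            n_pulses=config.n_pulses, n_repeats=config.n_repeats, seed=cell_seed)
        mask = result.ablated_masks[0]
    else:
        result = None
        mask = None
    grid = PolarGrid.for_section(
        section, dr_cm=config.transport_dr_cm,
        catheter_radius_cm=config.transport_params.catheter_radius_cm)
    cfield = transport.solve(section, mask, config.transport_params, grid,
                             duration_s=config.transport_duration_s)
    _, fdp_total = kinetics.fdp_map(cfield, section, mask, config.kinetic_params)
    return result, cfield, fdp_total


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full sweep; returns the per-repeat dose-response table.

    Columns: section, subgroup, fibrin_fraction, pressure_mpa, repeat,
    ablation_area_mm2, hemoglobin_ng, hemoglobin_catheter_ng, fdp_total,
    relative_fdp. FDP is computed once per (section, pressure) from the
    first repeat's ablation mask (the transport stage sees one mask), so
    it is constant across the repeat rows of a cell.
    """
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(out_dir / "config.yaml")

    cohort = generate_cohort(config)
    rows: list[dict] = []
    cell_seeds = np.random.SeedSequence([config.seed, 0xABA7]).generate_state(
        len(cohort) * len(config.pressures_mpa)) % (2**31 - 1)

    for i_sec, (sec_id, section) in enumerate(cohort):
        comp = histology.composition(section)
        hb_cath = montecarlo.catheter_hemolysis(
            section, config.transport_params.catheter_radius_cm * 10.0)
        baseline_fdp: float | None = None
        if out_dir:
            histology.write_label_mask(section, out_dir / f"{sec_id}.png")
        for i_p, pressure in enumerate(config.pressures_mpa):
            cell_seed = int(cell_seeds[i_sec * len(config.pressures_mpa) + i_p])
            try:
                result, cfield, fdp_total = _treat_cell(section, pressure, config, cell_seed)
            except Exception:
                log.exception("cell failed: section=%s pressure=%.1f MPa", sec_id, pressure)
                continue
            if pressure == 0:
                baseline_fdp = fdp_total
            rel = (fdp_total / baseline_fdp
                   if baseline_fdp is not None and baseline_fdp > 0 else np.nan)
            log.info("section=%s p=%.1f MPa fdp=%.3g rel=%.3g", sec_id, pressure,
                     fdp_total, rel)
            if result is None:
                areas = np.zeros(config.n_repeats)
                hb = np.zeros(config.n_repeats)
            else:
                areas = result.final_areas_mm2
                hb = result.hemoglobin_histotripsy_ng
                if out_dir:
                    mask_sec = HistologySection(
                        labels=np.where(result.ablated_masks[0],
                                        np.uint8(histology.Label.ABLATED), section.labels),
                        pixel_size_um=section.pixel_size_um)
                    histology.write_label_mask(
                        mask_sec, out_dir / f"{sec_id}_p{pressure:g}_ablation.png")
            for rep in range(config.n_repeats):
                rows.append(dict(
                    section=sec_id, subgroup=comp.subgroup.value,
                    fibrin_fraction=comp.fibrin_fraction,
                    pressure_mpa=pressure, repeat=rep,
                    ablation_area_mm2=float(areas[rep]),
                    hemoglobin_ng=float(hb[rep]),
                    hemoglobin_catheter_ng=hb_cath,
                    fdp_total=fdp_total, relative_fdp=rel,
                ))
    table = pd.DataFrame(rows)
    if out_dir:
        table.to_csv(out_dir / "dose_response.csv", index=False)
        summarize(table).to_csv(out_dir / "summary.csv", index=False)
    return table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-(section, pressure) means over repeats."""
    return (table.groupby(["section", "subgroup", "fibrin_fraction", "pressure_mpa"],
                          as_index=False)
            .agg(ablation_area_mm2=("ablation_area_mm2", "mean"),
                 hemoglobin_ng=("hemoglobin_ng", "mean"),
                 hemoglobin_catheter_ng=("hemoglobin_catheter_ng", "first"),
                 fdp_total=("fdp_total", "first"),
                 relative_fdp=("relative_fdp", "first")))


def zlrc_by_section(table: pd.DataFrame) -> pd.Series:
    """Z-score linear-regression coefficient (Hg vs FDP) per section.

    Uses per-pressure means over the >0 MPa sweep; sections with zero
    hemoglobin variance come out NaN (undefined, not zero).
    """
    s = summarize(table)
    s = s[s.pressure_mpa > 0]
    out = {}
    for sec, grp in s.groupby("section"):
        grp = grp.sort_values("pressure_mpa")
        out[sec] = linear_regression_coefficient(
            grp.hemoglobin_ng.to_numpy(), grp.fdp_total.to_numpy())
    return pd.Series(out, name="zlrc")
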