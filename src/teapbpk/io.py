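"""Series and scenario file I/O.

Concentration-time series are comma-separated text with a header row
(``time_h,conc_ug_per_ml``) and optional ``#`` comment lines carrying
provenance (study label, catechin, noise seed). Scenario configurations
are YAML. Output is plain decimal text, fixed column order, full
precision — bit-stable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .engine import SimulationResult
from .errors import DomainError, LookupError_, ParseError
from .evaluation import ObservedSeries
from .mixture import MixtureScenario
from .params import CATECHINS, SPECIES


def read_series(path: str | Path) -> ObservedSeries:
    """Read and validate a two-column (time, concentration) file.

    Rejects malformed rows (with the line number), unsorted times and
    negative concentrations. ``#`` lines and a single header row are
    skipped; header metadata of the form ``# key: value`` populates the
    series label and catechin.
    """
    path = Path(path)
    label, catechin = path.stem, ""
    times: list[float] = []
    concs: list[float] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    if key.strip().lower() in ("study", "label"):
                        label = value.strip()
                    elif key.strip().lower() == "catechin":
                        catechin = value.strip()
                continue
            fields = [f.strip() for f in line.split(",")]
            if fields and fields[0].lower() in ("time_h", "time"):
                continue  # header row
            if len(fields) != 2:
                raise ParseError(f"expected two columns, got {len(fields)}", lineno)
            try:
                t, c = float(fields[0]), float(fields[1])
            except ValueError:
                raise ParseError(f"non-numeric value in {fields!r}", lineno) from None
            if times and t <= times[-1]:
                raise ParseError(f"time {t} is not after {times[-1]}", lineno)
            if c < 0:
                raise ParseError(f"negative concentration {c}", lineno)
            times.append(t)
            concs.append(c)
    return ObservedSeries(tuple(times), tuple(concs), label=label,
                          catechin_id=catechin)


def write_series(series: ObservedSeries, path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if series.label:
            fh.write(f"# label: {series.label}\n")
        if series.catechin_id:
            fh.write(f"# catechin: {series.catechin_id}\n")
        fh.write("time_h,conc_ug_per_ml\n")
        for t, c in zip(series.times, series.concentrations):
            fh.write(f"{t:.12g},{c:.12g}\n")


def write_result(result: SimulationResult, path: str | Path) -> None:
    """Write a simulation as delimited text: time_h, one concentration
    column per compartment, plasma, cumulative urine and feces."""
    df = result.to_frame()
    df.to_csv(Path(path), index=False, float_format="%.12g")


@dataclass(frozen=True)
class ScenarioConfig:
    """A dosing scenario: who, what, how much, and the output contract."""

    species: str
    bw_kg: float
    members: tuple  # of (catechin, dose_mg_per_kg, study or None)
    t_end_h: float = 24.0
    output_step_h: float = 0.05
    rtol: float = 1e-8
    atol: float = 1e-10

    def __post_init__(self):
        if self.species not in SPECIES:
            raise LookupError_(
                f"unknown species {self.species!r}; valid: {list(SPECIES)}"
            )
        if self.bw_kg <= 0:
            raise DomainError("bw_kg must be positive")
        if self.t_end_h <= 0 or self.output_step_h <= 0:
            raise DomainError("t_end_h and output_step_h must be positive")
        if not self.members:
            raise DomainError("scenario needs at least one member")
        for cat, dose, _ in self.members:
            if cat not in CATECHINS:
                raise LookupError_(
                    f"unknown catechin {cat!r}; valid: {list(CATECHINS)}"
                )
            if dose < 0:
                raise DomainError("doses must be non-negative")

    def to_mixture(self) -> MixtureScenario:
        return MixtureScenario(self.species, self.bw_kg, tuple(self.members))


def read_scenario(path: str | Path) -> ScenarioConfig:
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh)
    return _scenario_from_dict(raw, str(path))


def _scenario_from_dict(raw: dict, source: str) -> ScenarioConfig:
    if not isinstance(raw, dict):
        raise ParseError(f"{source}: scenario must be a mapping")
    try:
        members = tuple(
            (m["catechin"], float(m["dose_mg_per_kg"]), m.get("study"))
            for m in raw["members"]
        )
        return ScenarioConfig(
            species=raw["species"],
            bw_kg=float(raw["bw_kg"]),
            members=members,
            t_end_h=float(raw.get("t_end_h", 24.0)),
            output_step_h=float(raw.get("output_step_h", 0.05)),
            rtol=float(raw.get("rtol", 1e-8)),
            atol=float(raw.get("atol", 1e-10)),
        )
    except KeyError as exc:
        raise ParseError(f"{source}: missing scenario key {exc}") from None


def write_scenario(config: ScenarioConfig, path: str | Path) -> None:
    """Lossless round-trip counterpart of :func:`read_scenario`."""
    doc = {
        "species": config.species,
        "bw_kg": config.bw_kg,
        "t_end_h": config.t_end_h,
        "output_step_h": config.output_step_h,
        "rtol": config.rtol,
        "atol": config.atol,
        "members": [
            {"catechin": c, "dose_mg_per_kg": d,
             **({"study": s} if s else {})}
            for c, d, s in config.members
        ],
    }
    with Path(path).open("w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def packaged_scenarios() -> dict[str, ScenarioConfig]:
    """The shipped example scenarios, keyed by file stem."""
    out: dict[str, ScenarioConfig] = {}
    root = resources.files("teapbpk.data").joinpath("scenarios")
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".yaml"):
            raw = yaml.safe_load(entry.read_text())
            out[entry.name[:-5]] = _scenario_from_dict(raw, entry.name)
    return out


__all__ = [
    "ScenarioConfig", "read_series", "write_series", "write_result",
    "read_scenario", "write_scenario", "packaged_scenarios",
]
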