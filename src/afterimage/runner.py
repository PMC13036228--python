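"""Experiment orchestration: stimuli -> network -> readout -> analysis.

``run_experiment`` builds the full afterimage network for a stimulus
sequence, simulates it, converts probed outputs to percept frames and
CIELAB metrics, and classifies afterimage polarity at the end of each
test stage.  ``preset_catalog`` enumerates the complete experimental
battery (closed contours in four colors and five configurations, star
pairs, spirals, alternating contours, adaptation-duration sweep), and
``run_battery`` executes it against the shipped expectations table.

For spiking runs the representational radius of each ensemble is first
calibrated from a fast rate-mode pass over the same stimulus (1.5x the
largest input observed, with a small floor), so population codes neither
saturate nor waste resolution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
import argparse
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nef_core as nef
from .adaptation_pathway import (
    CHANNELS,
    build_double_opponent,
    build_single_opponent_input,
)
from .analysis import PolarityResult, classify_polarity, mean_color, trajectory
from .color_space import TABLE1, lab_hue_chroma, srgb_to_cielab, xyy_to_srgb
from .filling_in import DiffusionParams, build_diffusion, build_luminance_filling
from .inducer import build_inducer, build_modulatory_signal
from .percept_readout import PerceptTrace, attach_percept_probes, build_percept_trace
from .stimuli import SPIRAL_RED, StimulusSpec, StimulusSequence, make_sequence

log = logging.getLogger(__name__)

__all__ = [
    "NetworkConfig",
    "ReadoutConfig",
    "AnalysisConfig",
    "ExperimentConfig",
    "ExperimentResult",
    "build_model",
    "calibrate_radii",
    "run_experiment",
    "preset_catalog",
    "PRESET_EXPECTATIONS",
    "run_battery",
    "main",
]


# ===========================================================================
# Configuration
# ===========================================================================


@dataclass(frozen=True)
class NetworkConfig:
    """All network hyperparameters (defaults are the reference values)."""

    k_rg: float = 5.0
    k_by: float = 5.0
    k_lum: float = 2.0
    tau_hp: float = 1.0  # adaptation high-pass time constant (s)
    tau_syn: float = 0.005  # default synaptic low-pass (s)
    alpha: float = 10.0  # inducer amplification factor
    beta: float = 100.0  # single-opponent inhibition factor
    c_r: float = 2.0
    c_i: float = 0.25
    tau_r: float = 0.01
    neurons_per_pixel: int = 20  # diffusion populations (reference: 200)
    max_rate: float = 200.0
    intercept_mag: float = 0.1  # one-polarity magnitude-mask intercept
    tau_rc: float = 0.02
    tau_ref: float = 0.002
    dt: float = 0.001
    seed: int = 0
    mode: str = "spiking"  # spiking | rate
    radius_margin: float = 1.5
    radius_floor: float = 0.05

    @property
    def k(self) -> dict[str, float]:
        return {"rg": self.k_rg, "by": self.k_by, "lum": self.k_lum}

    @property
    def diffusion(self) -> DiffusionParams:
        return DiffusionParams(
            self.c_r, self.c_i, self.tau_r, self.neurons_per_pixel, self.tau_rc, self.tau_ref
        )


@dataclass(frozen=True)
class ReadoutConfig:
    probe_tau: float = 0.05
    sample_every: float = 0.05
    no_anchor: str = "carry"  # carry | identity


@dataclass(frozen=True)
class AnalysisConfig:
    hue_window_deg: float = 60.0
    chroma_threshold: float = 1.0
    region: str = "interior_full"
    #: percepts are classified on the average frame over this window at
    #: the end of each test stage (short: the percept can still be
    #: evolving through a sign change late in a stage; a few samples
    #: suffice to steady the spiking readout)
    classify_window_s: float = 0.15


@dataclass(frozen=True)
class ExperimentConfig:
    stimulus: StimulusSpec
    network: NetworkConfig = NetworkConfig()
    readout: ReadoutConfig = ReadoutConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    reference_color: str | None = None  # palette key or None -> inducer_color

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stimulus"]["stage_durations"] = list(self.stimulus.stage_durations)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        stim = dict(d["stimulus"])
        stim["stage_durations"] = tuple(stim["stage_durations"])
        try:
            return cls(
                stimulus=StimulusSpec(**stim),
                network=NetworkConfig(**d.get("network", {})),
                readout=ReadoutConfig(**d.get("readout", {})),
                analysis=AnalysisConfig(**d.get("analysis", {})),
                reference_color=d.get("reference_color"),
            )
        except TypeError as err:
            raise ValueError(f"invalid experiment config: {err}") from err

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


# ===========================================================================
# Model assembly
# ===========================================================================


def build_model(
    sequence: StimulusSequence,
    cfg: NetworkConfig,
    radii: dict[str, float] | None = None,
    probe_internal: bool = False,
    readout: ReadoutConfig = ReadoutConfig(),
):
    """Assemble the full network for one stimulus sequence.

    Returns ``(net, percept_probes, internal_probes)``.
    """
    shape = sequence.shape
    d = shape[0] * shape[1]
    net = nef.Network(label="afterimage")
    so_nodes = build_single_opponent_input(net, sequence)
    # double-opponent and decomposition stages are rectified-linear and
    # do not saturate: they keep the fixed unit radius of the reference
    # configuration, which also fixes the duty-cycle gating scale
    do = build_double_opponent(
        net, so_nodes, shape, cfg.k, tau_syn=cfg.tau_syn, max_rate=cfg.max_rate
    )
    c_ens = build_modulatory_signal(
        net, so_nodes, do["lum"], shape, cfg.beta,
        intercept=cfg.intercept_mag, tau_syn=cfg.tau_syn, radii=radii,
    )
    fill = {}
    for ch in ("rg", "by"):
        e_node = build_inducer(
            net, do[ch], c_ens, d, ch, cfg.alpha, cfg.tau_hp,
            tau_syn=cfg.tau_syn, mode=cfg.mode,
        )
        fill[ch] = build_diffusion(
            net, e_node, shape, cfg.diffusion, label=f"fill_{ch}",
            radius=(radii or {}).get(f"fill_{ch}", 1.0),
        )
    fill["lum"] = build_luminance_filling(
        net, do["lum"], shape, cfg.diffusion, radius=(radii or {}).get("fill_lum", 1.0)
    )
    percept_probes = attach_percept_probes(
        net, fill, probe_tau=readout.probe_tau, sample_every=readout.sample_every
    )
    internal_probes = {}
    if probe_internal:
        internal_probes["c_gate"] = net.probe(
            c_ens, synapse=nef.Lowpass(0.02), sample_every=0.01, label="c_gate"
        )
        for ch in ("rg", "by"):
            for node in net.nodes:
                if node.label == f"inducer_{ch}":
                    internal_probes[f"inducer_{ch}"] = net.probe(
                        node, synapse=None, sample_every=0.01, label=f"inducer_{ch}"
                    )
        for ch in CHANNELS:
            internal_probes[f"do_{ch}"] = net.probe(
                do[ch], synapse=nef.Lowpass(0.02), sample_every=0.01, label=f"do_{ch}"
            )
    return net, percept_probes, internal_probes


def calibrate_radii(
    sequence: StimulusSequence, cfg: NetworkConfig, iterations: int = 2
) -> dict[str, float]:
    """Radii from rate-mode passes: ``margin * max |input|`` per ensemble.

    Because the one-polarity magnitude thresholds scale with the radius,
    the signal ranges themselves depend on the radii; two passes suffice
    for the ranges to settle.
    """
    radii: dict[str, float] | None = None
    for _ in range(max(1, iterations)):
        net, _, _ = build_model(sequence, cfg, radii=radii)
        sim = nef.Simulator(net, dt=cfg.dt, seed=cfg.seed, mode="rate")
        sim.run(sequence.duration)
        radii = {
            label: max(cfg.radius_margin * reach, cfg.radius_floor)
            for label, reach in sim.input_ranges().items()
        }
        _share_chromatic_radii(radii)
    return radii


#: Ensemble groups that must share one representational radius: the two
#: chromatic channels are encoded on a common scale, so that a channel
#: carrying only a trace of signal keeps its (small) place relative to
#: the channel carrying the stimulus instead of being renormalized to
#: full sensitivity.
_RADIUS_GROUPS = (
    ("do_rg", "do_by"),
    ("ada_rg_pos", "ada_rg_neg", "ada_by_pos", "ada_by_neg"),
    ("mag_so_rg_pos", "mag_so_rg_neg", "mag_so_by_pos", "mag_so_by_neg"),
)


def _share_chromatic_radii(radii: dict[str, float]) -> None:
    for group in _RADIUS_GROUPS:
        present = [g for g in group if g in radii]
        if present:
            shared = max(radii[g] for g in present)
            for g in present:
                radii[g] = shared


# ===========================================================================
# Experiment runner
# ===========================================================================


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    sequence: StimulusSequence
    percept: PerceptTrace
    metrics: pd.DataFrame  # time x region CIELAB table
    classifications: list[PolarityResult]  # one per test stage
    radii: dict[str, float]
    internal: dict = field(default_factory=dict)

    @property
    def reference_hue(self) -> float:
        return _reference_hue(self.config)

    def manifest(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "radii": self.radii,
            "classifications": [asdict(c) for c in self.classifications],
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sequence.write_pngs(out / "stimulus")
        self.percept.write_pngs(out / "percepts")
        self.metrics.to_csv(out / "metrics.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest(), indent=2))


def _reference_hue(config: ExperimentConfig) -> float:
    """CIELAB hue of the color against which polarity is judged."""
    name = config.reference_color or config.stimulus.inducer_color
    if config.stimulus.family == "spiral":
        rgb = SPIRAL_RED
    else:
        rgb = TABLE1[name][1]
    hue, _ = lab_hue_chroma(srgb_to_cielab(np.array(rgb)))
    return hue


def run_experiment(config: ExperimentConfig, probe_internal: bool = False) -> ExperimentResult:
    """Simulate one experiment end to end."""
    cfg = config.network
    sequence = make_sequence(config.stimulus)
    radii = calibrate_radii(sequence, cfg)
    net, percept_probes, internal_probes = build_model(
        sequence, cfg, radii=radii, probe_internal=probe_internal, readout=config.readout
    )
    sim = nef.Simulator(net, dt=cfg.dt, seed=cfg.seed, mode=cfg.mode)
    traces = sim.run(sequence.duration)
    percept = build_percept_trace(
        {ch: traces[percept_probes[ch]] for ch in CHANNELS},
        sequence,
        no_anchor=config.readout.no_anchor,
        drift_correct=(cfg.mode == "spiking"),
    )
    metrics = _region_metrics(percept, sequence)
    classifications = _classify_stages(percept, sequence, config)
    internal = {name: traces[probe] for name, probe in internal_probes.items()}
    return ExperimentResult(config, sequence, percept, metrics, classifications, radii, internal)


def _region_metrics(percept: PerceptTrace, sequence: StimulusSequence) -> pd.DataFrame:
    frames_regions = []
    for name, mask in sequence.masks.items():
        if name in ("contour",) or not mask.any():
            continue
        df = trajectory(percept.frames, percept.times, mask)
        df.insert(1, "region", name)
        frames_regions.append(df)
    return pd.concat(frames_regions, ignore_index=True)


def _stage_end_index(times: np.ndarray, t_end: float) -> int:
    ok = np.flatnonzero(times <= t_end + 1e-9)
    return int(ok[-1]) if len(ok) else 0


def _classify_stages(
    percept: PerceptTrace, sequence: StimulusSequence, config: ExperimentConfig
) -> list[PolarityResult]:
    region = sequence.masks[config.analysis.region]
    ref_hue = _reference_hue(config)
    results = []
    bounds = sequence.stage_boundaries
    window = config.analysis.classify_window_s
    for stage in range(1, len(sequence.frames)):
        t_end = bounds[stage]
        sel = (percept.times <= t_end + 1e-9) & (percept.times > t_end - window - 1e-9)
        if not sel.any():
            sel = np.zeros(len(percept.times), dtype=bool)
            sel[_stage_end_index(percept.times, t_end)] = True
        # average in opponent space before display saturation (temporal
        # noise reduction) and judge chroma at the scene's background
        # luminance, where CIELAB chroma is not crushed by dark pixels
        lum_ref = float(np.median(sequence.opponent_at(t_end - 1e-3)[2]))
        lab = mean_color(percept.mean_frame(sel, lum_override=lum_ref), region)
        results.append(
            classify_polarity(
                lab, ref_hue, config.analysis.hue_window_deg, config.analysis.chroma_threshold
            )
        )
    return results


# ===========================================================================
# Preset battery
# ===========================================================================

_COLORS = ("green", "orange", "blue", "pink")


def preset_catalog(image_size: int = 24, fast: bool = True) -> dict[str, ExperimentConfig]:
    """The full battery of named experiments.

    ``fast`` selects the desk-scale neuron budget (20 LIF per pixel) and
    a common small grid; the reference budget (200 LIF per pixel, native
    grid sizes 36/50) is obtained with ``fast=False``.
    """
    net = NetworkConfig(neurons_per_pixel=20 if fast else 200)
    size_contour = image_size if fast else 36
    size_big = image_size if fast else 50
    cat: dict[str, ExperimentConfig] = {}
    for color in _COLORS:
        for config in ("null", "I", "II", "III", "IV"):
            name = f"contour-{config}-{color}"
            # the destructive condition is judged on the fringe-free
            # interior: cancellation concerns the filling-in proper, not
            # the local afterimages hugging the adapted contours
            analysis = (
                AnalysisConfig(region="interior_excl_adapted")
                if config == "IV"
                else AnalysisConfig()
            )
            cat[name] = ExperimentConfig(
                StimulusSpec("contour", config, color, size_contour), net, analysis=analysis
            )
    star_analysis = AnalysisConfig(region="star_overlap")
    cat["star-plain"] = ExperimentConfig(
        StimulusSpec("star", "star_plain", image_size=size_big), net,
        analysis=star_analysis, reference_color="red_star",
    )
    cat["star-inner"] = ExperimentConfig(
        StimulusSpec("star", "star_inner", image_size=size_big), net,
        analysis=star_analysis, reference_color="red_star",
    )
    for order in ("ab", "ba"):
        cat[f"star-alt-{order}"] = ExperimentConfig(
            StimulusSpec("star", f"alt_star_{order}", image_size=size_big,
                         stage_durations=(1.0, 1.0, 1.0)),
            net, analysis=star_analysis, reference_color="red_star",
        )
    for order in ("inner_outer", "outer_inner"):
        cat[f"contour-alt-{order}"] = ExperimentConfig(
            StimulusSpec("contour", f"alt_{order}", "green", size_contour,
                         stage_durations=(1.0, 1.0, 1.0)),
            net, analysis=AnalysisConfig(region="core"),
        )
    size_spiral = max(30, image_size) if fast else 50
    for variant in ("full", "outer", "inner"):
        for invert in (False, True):
            suffix = "-inv" if invert else ""
            region = "spiral_interior" if variant != "full" else "inside_spiral"
            cat[f"spiral-{variant}{suffix}"] = ExperimentConfig(
                StimulusSpec("spiral", f"spiral_{variant}", image_size=size_spiral, invert=invert),
                net, analysis=AnalysisConfig(region=region),
            )
    for dur in (0.25, 0.5, 1.0, 2.0):
        cat[f"null-green-t{dur}"] = ExperimentConfig(
            StimulusSpec("contour", "null", "green", size_contour, stage_durations=(dur, 1.0)),
            net,
        )
    return cat


def _expectations() -> dict[str, list[str]]:
    exp: dict[str, list[str]] = {}
    for color in _COLORS:
        exp[f"contour-null-{color}"] = ["negative"]
        exp[f"contour-I-{color}"] = ["negative"]
        exp[f"contour-II-{color}"] = ["positive"]
        # III is labelled by the outer (complementary) contour's positive
        # effect, i.e. the complement of the inducer
        exp[f"contour-III-{color}"] = ["negative"]
        # IV: cancellation is checked as an ordering (chroma below both
        # single conditions), not as an absolute label
        exp[f"contour-IV-{color}"] = [None]
    exp["star-plain"] = ["negative"]
    exp["star-inner"] = ["negative"]
    exp["star-alt-ab"] = ["negative", "positive"]
    exp["star-alt-ba"] = ["positive", "negative"]
    exp["contour-alt-inner_outer"] = ["positive", "negative"]
    exp["contour-alt-outer_inner"] = ["negative", "positive"]
    exp["spiral-full"] = ["positive"]
    exp["spiral-outer"] = ["positive"]
    exp["spiral-inner"] = ["negative"]
    exp["spiral-full-inv"] = ["negative"]
    exp["spiral-outer-inv"] = ["negative"]
    exp["spiral-inner-inv"] = ["positive"]
    for dur in (0.25, 0.5, 1.0, 2.0):
        exp[f"null-green-t{dur}"] = ["negative"]
    return exp


#: Expected polarity per test stage for every preset.
PRESET_EXPECTATIONS: dict[str, list[str]] = _expectations()


def run_battery(
    names: list[str] | None = None,
    image_size: int = 24,
    seed: int = 0,
    mode: str = "spiking",
    progress: bool = False,
) -> pd.DataFrame:
    """Run (part of) the preset battery; returns one row per test stage."""
    catalog = preset_catalog(image_size=image_size)
    names = names or list(catalog)
    rows = []
    results = {}
    for name in names:
        config = catalog[name]
        config = replace(config, network=replace(config.network, seed=seed, mode=mode))
        result = run_experiment(config)
        results[name] = result
        expected = PRESET_EXPECTATIONS.get(name, [])
        for stage, cls in enumerate(result.classifications):
            want = expected[stage] if stage < len(expected) else None
            rows.append(
                {
                    "preset": name,
                    "stage": stage + 1,
                    "classification": cls.label,
                    "expected": want,
                    "ok": (cls.label == want) if want else None,
                    "hue_deg": cls.hue_deg,
                    "chroma": cls.chroma,
                }
            )
        if progress:
            print(f"{name}: " + ", ".join(c.label for c in result.classifications))
    df = pd.DataFrame(rows)
    df.attrs["results"] = results
    return df


# ===========================================================================
# CLI
# ===========================================================================


def _cmd_run(args) -> int:
    catalog = preset_catalog(image_size=args.size)
    if args.preset:
        config = catalog[args.preset]
    else:
        config = ExperimentConfig.load(args.config)
    config = replace(
        config,
        network=replace(config.network, seed=args.seed, mode=args.mode),
    )
    result = run_experiment(config)
    out = Path(args.out or "afterimage_out")
    result.save(out)
    for stage, cls in enumerate(result.classifications, start=1):
        print(f"stage {stage}: {cls.label} (hue {cls.hue_deg:.1f} deg, chroma {cls.chroma:.2f})")
    print(f"artifacts written to {out}")
    return 0


def _cmd_stimgen(args) -> int:
    spec = StimulusSpec(
        family=args.family,
        configuration=args.config,
        inducer_color=args.color,
        image_size=args.size,
    )
    seq = make_sequence(spec)
    seq.write_pngs(args.out)
    print(f"{len(seq.frames)} stages written to {args.out}")
    return 0


def _cmd_check_table1(args) -> int:
    rows = []
    for name, (xyy, srgb) in TABLE1.items():
        got = xyy_to_srgb(xyy)
        rows.append(
            {"color": name, "x": xyy.x, "y": xyy.y, "Y": xyy.Y,
             "expected": srgb, "computed": got,
             "max_abs_diff": max(abs(a - b) for a, b in zip(got, srgb))}
        )
    df = pd.DataFrame(rows)
    print(df.to_string(index=False))
    if args.out:
        df.to_csv(args.out, index=False)
    return int((df["max_abs_diff"] > 1).any())


def _cmd_battery(args) -> int:
    df = run_battery(image_size=args.size, seed=args.seed, mode=args.mode, progress=True)
    checked = df[df["expected"].notna()]
    n_ok = int(checked["ok"].sum())
    print(f"\n{n_ok}/{len(checked)} stage classifications match expectations")
    if args.out:
        df.drop(columns=[]).to_csv(args.out, index=False)
    return int(n_ok < len(checked))


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(
        prog="afterimage",
        description="Spiking-network simulation of contour-induced color afterimages",
    )
    sub = parser.add_subparsers(dest="command", required=True)

    p_run = sub.add_parser("run", help="run one experiment")
    p_run.add_argument("--preset", help="preset name (see battery)")
    p_run.add_argument("--config", help="YAML experiment config")
    p_run.add_argument("--seed", type=int, default=0)
    p_run.add_argument("--mode", choices=("spiking", "rate"), default="spiking")
    p_run.add_argument("--size", type=int, default=24)
    p_run.add_argument("--out")
    p_run.set_defaults(func=_cmd_run)

    p_stim = sub.add_parser("stimgen", help="generate stimulus PNGs")
    p_stim.add_argument("--family", default="contour")
    p_stim.add_argument("--config", default="I")
    p_stim.add_argument("--color", default="green")
    p_stim.add_argument("--size", type=int, default=36)
    p_stim.add_argument("--out", default="stimuli_out")
    p_stim.set_defaults(func=_cmd_stimgen)

    p_tab = sub.add_parser("check-table1", help="verify palette conversions")
    p_tab.add_argument("--out")
    p_tab.set_defaults(func=_cmd_check_table1)

    p_bat = sub.add_parser("battery", help="run the full preset battery")
    p_bat.add_argument("--size", type=int, default=24)
    p_bat.add_argument("--seed", type=int, default=0)
    p_bat.add_argument("--mode", choices=("spiking", "rate"), default="spiking")
    p_bat.add_argument("--out")
    p_bat.set_defaults(func=_cmd_battery)

    args = parser.parse_args(argv)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    return args.func(args)


if __name__ == "__main__":  # pragma: no cover
    raise SystemExit(main())
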