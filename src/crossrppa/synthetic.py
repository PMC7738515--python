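"""Synthetic multi-platform RPPA study generation.

Emulates a three-site reverse-phase protein array (RPPA) study of breast
cancer cell lines: a factorial treatment design (cell line x drug x
timepoint x biological replicate), latent log2 antigen abundances with
cell-line baselines and drug-response effects, and per-platform rendering
into spot-level linear fluorescence intensities with serial two-fold
dilution series, technical replicate spots, platform gains/offsets and a
detection floor.

The generator provides known ground truth (the latent antigen matrix and
the effect table actually applied), so every downstream processing,
integration, clustering and testing stage can be validated without any
external data.  All randomness flows from a single integer seed through
named sub-streams, making every output reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError, DesignError, SchemaError

__all__ = [
    "SampleRecord",
    "StudyDesign",
    "DrugEffect",
    "AntigenConfig",
    "LatentAntigenMatrix",
    "AntibodyProbe",
    "PlatformConfig",
    "PlatformRender",
    "SyntheticStudy",
    "derive_seed",
    "generate_design",
    "design_frame",
    "generate_latent_antigens",
    "render_platform",
    "simulate_study",
    "default_design",
    "default_antigen_config",
    "default_platforms",
    "raw_annotation_table",
    "ANTIGEN_CLASSES",
    "DEFAULT_SENSITIVITY",
    "DEFAULT_SYNONYMS",
]


def derive_seed(seed: int, label: str) -> int:
    """Derive a per-stage seed (< 2**31) from a top-level seed and a label."""
    digest = hashlib.sha256(f"{seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# study design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleRecord:
    """One biological lysate in the study."""

    sample_id: str
    cell_line: str
    receptor_status: str
    treatment: str
    timepoint_min: int
    replicate: int


@dataclass
class StudyDesign:
    """Full factorial design: cell lines x treatments x timepoints x replicates."""

    cell_lines: list[tuple[str, str]]  # (name, receptor status)
    treatments: list[str]
    timepoints_min: list[int]
    n_replicates: int

    def validate(self) -> None:
        if not self.cell_lines or not self.treatments or not self.timepoints_min:
            raise DesignError("all design factors must be non-empty")
        if self.n_replicates < 1:
            raise DesignError("n_replicates must be >= 1")
        names = [c for c, _ in self.cell_lines]
        if len(set(names)) != len(names):
            raise DesignError("duplicate cell line names")

    @property
    def n_samples(self) -> int:
        return (
            len(self.cell_lines)
            * len(self.treatments)
            * len(self.timepoints_min)
            * self.n_replicates
        )


def generate_design(design: StudyDesign) -> list[SampleRecord]:
    """Expand a design into its deterministic, fully factorial sample list.

    Order is (cell line, treatment, timepoint, replicate), matching the
    order of the factor lists.
    """
    design.validate()
    samples: list[SampleRecord] = []
    for cell, status in design.cell_lines:
        for treatment in design.treatments:
            for tp in design.timepoints_min:
                for rep in range(1, design.n_replicates + 1):
                    sid = f"{cell}.{treatment}.{tp}min.r{rep}"
                    samples.append(
                        SampleRecord(sid, cell, status, treatment, tp, rep)
                    )
    return samples


def design_frame(samples: list[SampleRecord]) -> pd.DataFrame:
    """Sample annotation table indexed by sample_id."""
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "cell_line": [s.cell_line for s in samples],
            "receptor_status": [s.receptor_status for s in samples],
            "treatment": [s.treatment for s in samples],
            "timepoint_min": [s.timepoint_min for s in samples],
            "replicate": [s.replicate for s in samples],
        }
    )
    return df.set_index("sample_id")


# ---------------------------------------------------------------------------
# latent antigen abundances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DrugEffect:
    """A true log2 treatment effect on one antigen class.

    ``timepoint_min=None`` applies the effect at every timepoint.  Effects
    act only in cell lines flagged sensitive to the treatment.
    """

    antigen: str
    treatment: str
    timepoint_min: int | None
    log2_change: float


@dataclass
class AntigenConfig:
    """Latent-abundance model parameters.

    Each (antigen, cell line) baseline is a cell-line factor times a
    per-antigen loading (shared co-regulation: most proteins co-vary
    weakly and positively across cell lines with overall abundance, which
    is what makes unrelated antibodies mildly correlated in real data)
    plus an independent draw of spread ``baseline_sd``.  Loadings are
    drawn around ``coregulation_mean`` with spread ``coregulation_sd``.
    Biological replicate noise has spread ``replicate_sd``.  All values
    are on the log2 scale.
    """

    antigens: list[str]
    baseline_sd: float = 1.0
    coregulation_mean: float = 0.4
    coregulation_sd: float = 0.35
    replicate_sd: float = 0.25
    effects: list[DrugEffect] = field(default_factory=list)
    sensitive: dict[str, frozenset[str]] = field(default_factory=dict)

    def validate(self, samples: list[SampleRecord]) -> None:
        if not self.antigens:
            raise ConfigError("antigen list must be non-empty")
        if len(set(self.antigens)) != len(self.antigens):
            raise ConfigError("duplicate antigen class names")
        if self.replicate_sd < 0 or self.baseline_sd < 0 or self.coregulation_sd < 0:
            raise ConfigError("noise standard deviations must be >= 0")
        cells = {s.cell_line for s in samples}
        treatments = {s.treatment for s in samples}
        timepoints = {s.timepoint_min for s in samples}
        for e in self.effects:
            if e.antigen not in self.antigens:
                raise ConfigError(f"effect references unknown antigen {e.antigen!r}")
            if e.treatment not in treatments:
                raise ConfigError(f"effect references unknown treatment {e.treatment!r}")
            if e.timepoint_min is not None and e.timepoint_min not in timepoints:
                raise ConfigError(
                    f"effect references unknown timepoint {e.timepoint_min!r}"
                )
        for treatment, lines in self.sensitive.items():
            unknown = set(lines) - cells
            if unknown:
                raise ConfigError(
                    f"sensitivity flags reference unknown cell lines {sorted(unknown)}"
                )


@dataclass
class LatentAntigenMatrix:
    """True log2 abundances (antigen classes x samples) plus the applied effects."""

    values: pd.DataFrame  # index: antigen class, columns: sample_id
    effect_table: pd.DataFrame  # antigen, cell_line, treatment, timepoint_min, log2_change


def generate_latent_antigens(
    samples: list[SampleRecord], config: AntigenConfig, seed: int
) -> LatentAntigenMatrix:
    """Simulate true antigen abundances for every sample.

    value = baseline(antigen, cell line)
          + effect(antigen, treatment, timepoint)   [sensitive lines only]
          + Normal(0, replicate_sd)
    """
    config.validate(samples)
    antigens = list(config.antigens)
    cells = sorted({s.cell_line for s in samples})

    rng_base = np.random.default_rng(derive_seed(seed, "latent-baselines"))
    cell_factor = {c: rng_base.normal(0.0, 1.0) for c in cells}
    loading = rng_base.normal(
        config.coregulation_mean, config.coregulation_sd, len(antigens)
    )
    baseline = {
        (a, c): loading[i] * cell_factor[c] + rng_base.normal(0.0, config.baseline_sd)
        for i, a in enumerate(antigens)
        for c in cells
    }

    rng_noise = np.random.default_rng(derive_seed(seed, "latent-replicates"))
    noise = rng_noise.normal(0.0, config.replicate_sd, (len(antigens), len(samples)))

    values = np.empty((len(antigens), len(samples)))
    applied: list[dict] = []
    for j, s in enumerate(samples):
        sens = config.sensitive.get(s.treatment, frozenset())
        for i, a in enumerate(antigens):
            v = baseline[(a, s.cell_line)]
            for e in config.effects:
                if (
                    e.antigen == a
                    and e.treatment == s.treatment
                    and (e.timepoint_min is None or e.timepoint_min == s.timepoint_min)
                    and s.cell_line in sens
                ):
                    v += e.log2_change
                    applied.append(
                        {
                            "antigen": a,
                            "cell_line": s.cell_line,
                            "treatment": s.treatment,
                            "timepoint_min": s.timepoint_min,
                            "log2_change": e.log2_change,
                        }
                    )
            values[i, j] = v + noise[i, j]

    effect_table = (
        pd.DataFrame(applied).drop_duplicates().reset_index(drop=True)
        if applied
        else pd.DataFrame(
            columns=["antigen", "cell_line", "treatment", "timepoint_min", "log2_change"]
        )
    )
    frame = pd.DataFrame(values, index=antigens, columns=[s.sample_id for s in samples])
    return LatentAntigenMatrix(values=frame, effect_table=effect_table)


# ---------------------------------------------------------------------------
# platform rendering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AntibodyProbe:
    """One antibody in a platform panel.

    ``antigen`` is the ground-truth class the probe reads out; ``targets``
    are the raw declared target descriptions used downstream to exercise
    antigen classification (defaults to the class itself).  ``gain`` and
    ``offset`` act on the log2 scale; ``noise_sd`` is log2 spot noise.
    """

    antibody_id: str
    antigen: str
    supplier_ref: str
    phospho_site: str = ""
    gain: float = 1.0
    offset: float = 0.0
    noise_sd: float = 0.15
    targets: tuple[str, ...] = ()

    def declared_targets(self) -> tuple[str, ...]:
        return self.targets if self.targets else (self.antigen,)


@dataclass
class PlatformConfig:
    """One RPPA platform's set-up: panel, dilution series and noise model."""

    platform_id: str
    panel: list[AntibodyProbe]
    n_dilution_steps: int = 4
    n_technical_replicates: int = 2
    detection_floor: float = 1.0
    loading_sd: float = 0.0  # per-sample log2 loading variation (total protein)
    total_protein_base: float = 12.0  # log2 stain intensity at nominal loading

    def validate(self) -> None:
        if not self.panel:
            raise ConfigError(f"{self.platform_id}: empty antibody panel")
        ids = [p.antibody_id for p in self.panel]
        if len(set(ids)) != len(ids):
            raise ConfigError(f"{self.platform_id}: duplicate antibody ids")
        for p in self.panel:
            if p.gain <= 0:
                raise ConfigError(f"{self.platform_id}/{p.antibody_id}: gain must be > 0")
            if p.noise_sd < 0:
                raise ConfigError(
                    f"{self.platform_id}/{p.antibody_id}: noise_sd must be >= 0"
                )
        if self.n_dilution_steps < 1:
            raise ConfigError(f"{self.platform_id}: n_dilution_steps must be >= 1")
        if self.n_technical_replicates < 1:
            raise ConfigError(f"{self.platform_id}: n_technical_replicates must be >= 1")
        if self.detection_floor < 0 or self.loading_sd < 0:
            raise ConfigError(f"{self.platform_id}: negative floor or loading_sd")


@dataclass
class PlatformRender:
    """Spot-level output of one platform plus ground-truth provenance."""

    spots: pd.DataFrame  # sample_id, antibody_id, dilution_step, technical_replicate, intensity
    total_protein: pd.Series  # per-sample linear stain intensity
    provenance: dict


def render_platform(
    latent: LatentAntigenMatrix, pconfig: PlatformConfig, seed: int
) -> PlatformRender:
    """Render latent antigen abundances into a spot-level intensity table.

    Undiluted log2 signal = gain * latent + offset + sample loading + spot
    noise; each serial dilution step subtracts exactly 1.0 on the log2
    scale (two-fold); linear intensities are censored at the detection
    floor.  Every configured (dilution step, technical replicate) spot is
    emitted for every (sample, antibody).
    """
    pconfig.validate()
    missing = {p.antigen for p in pconfig.panel} - set(latent.values.index)
    if missing:
        raise SchemaError(
            f"{pconfig.platform_id}: panel references antigen classes absent from "
            f"the latent matrix: {sorted(missing)}"
        )

    sample_ids = list(latent.values.columns)
    n_s = len(sample_ids)
    n_ab = len(pconfig.panel)
    n_d = pconfig.n_dilution_steps
    n_t = pconfig.n_technical_replicates

    gains = np.array([p.gain for p in pconfig.panel])
    offsets = np.array([p.offset for p in pconfig.panel])
    noise_sd = np.array([p.noise_sd for p in pconfig.panel])
    lat = latent.values.loc[[p.antigen for p in pconfig.panel]].to_numpy()  # ab x s

    rng = np.random.default_rng(derive_seed(seed, f"render:{pconfig.platform_id}"))
    loading = (
        rng.normal(0.0, pconfig.loading_sd, n_s)
        if pconfig.loading_sd > 0
        else np.zeros(n_s)
    )
    noise = rng.standard_normal((n_ab, n_s, n_d, n_t)) * noise_sd[:, None, None, None]

    base = gains[:, None] * lat + offsets[:, None] + loading[None, :]
    steps = np.arange(n_d, dtype=float)
    log2_signal = base[:, :, None, None] - steps[None, None, :, None] + noise
    intensity = np.power(2.0, log2_signal)
    floored = intensity < pconfig.detection_floor
    intensity = np.maximum(intensity, pconfig.detection_floor)

    # row order: sample-major, then antibody, dilution step, technical replicate
    inten = np.transpose(intensity, (1, 0, 2, 3)).ravel()
    spots = pd.DataFrame(
        {
            "sample_id": np.repeat(sample_ids, n_ab * n_d * n_t),
            "antibody_id": np.tile(
                np.repeat([p.antibody_id for p in pconfig.panel], n_d * n_t), n_s
            ),
            "dilution_step": np.tile(np.repeat(np.arange(n_d), n_t), n_s * n_ab),
            "technical_replicate": np.tile(np.arange(1, n_t + 1), n_s * n_ab * n_d),
            "intensity": inten,
        }
    )
    total_protein = pd.Series(
        np.power(2.0, pconfig.total_protein_base + loading),
        index=pd.Index(sample_ids, name="sample_id"),
        name="total_protein",
    )
    provenance = {
        "platform_id": pconfig.platform_id,
        "seed": seed,
        "n_spots": int(spots.shape[0]),
        "n_floored_spots": int(floored.sum()),
        "detection_floor": pconfig.detection_floor,
    }
    return PlatformRender(spots=spots, total_protein=total_protein, provenance=provenance)


# ---------------------------------------------------------------------------
# study defaults: six breast cancer lines, two drugs, three platforms
# ---------------------------------------------------------------------------

#: Antigen classes shared by all three default panels (27 classes).
ANTIGEN_CLASSES = [
    "4EBP1_pT37/T46",
    "Akt",
    "Akt_pS473",
    "Bax",
    "Bcl2",
    "CyclinD1",
    "EGFR",
    "EGFR_pY1068",
    "Erk1/2",
    "Erk1/2_pT202/Y204",
    "GSK3b_pS9",
    "Her2",
    "Her2_pY1248",
    "JNK_pT183/Y185",
    "Mek1/2_pS217/S221",
    "PKCa",
    "PTEN",
    "Rb_pS807/S811",
    "S6",
    "S6_pS235/S236",
    "Src_pY416",
    "Stat3_pY705",
    "cMyc",
    "mTOR",
    "mTOR_pS2448",
    "p38_pT180/Y182",
    "p53",
]

#: Which cell lines respond to which drug (benchmark assumptions, not
#: estimates: Her2-amplified lines respond to the EGFR/Her2 inhibitor
#: lapatinib, triple-negative lines with active MAPK signalling respond to
#: the MEK inhibitor selumetinib; MCF7 responds to neither).
DEFAULT_SENSITIVITY: dict[str, frozenset[str]] = {
    "lapatinib": frozenset({"SKBR3", "HCC1954"}),
    "selumetinib": frozenset({"MDA-MB-231", "MDA-MB-468"}),
}

#: Raw target description -> canonical antigen class (isoform/family merges).
DEFAULT_SYNONYMS: dict[str, str] = {
    "Erk1": "Erk1/2",
    "Erk2": "Erk1/2",
    "p44/42 MAPK": "Erk1/2",
    "Mek1": "Mek1/2_pS217/S221",
    "Akt1": "Akt",
    "Akt1/2/3": "Akt",
}


def default_design() -> StudyDesign:
    """Six breast cancer cell lines x 3 treatments x 2 timepoints x 3 replicates."""
    return StudyDesign(
        cell_lines=[
            ("MCF7", "ER+"),
            ("MDA-MB-231", "TN"),
            ("MDA-MB-468", "TN"),
            ("MDA-MB-453", "Her2+"),
            ("HCC1954", "Her2+"),
            ("SKBR3", "Her2+"),
        ],
        treatments=["DMSO", "lapatinib", "selumetinib"],
        timepoints_min=[20, 1440],
        n_replicates=3,
    )


def _default_effects() -> list[DrugEffect]:
    e = DrugEffect
    return [
        # EGFR/Her2 inhibition: receptor and downstream AKT/ERK phospho-signals fall
        e("Her2_pY1248", "lapatinib", 20, -2.0),
        e("Her2_pY1248", "lapatinib", 1440, -2.5),
        e("EGFR_pY1068", "lapatinib", 20, -1.5),
        e("EGFR_pY1068", "lapatinib", 1440, -2.0),
        e("Akt_pS473", "lapatinib", 20, -1.0),
        e("Akt_pS473", "lapatinib", 1440, -1.8),
        e("Erk1/2_pT202/Y204", "lapatinib", 20, -1.0),
        e("Erk1/2_pT202/Y204", "lapatinib", 1440, -1.5),
        e("S6_pS235/S236", "lapatinib", 1440, -1.5),
        e("Rb_pS807/S811", "lapatinib", 1440, -1.0),
        e("CyclinD1", "lapatinib", 1440, -0.8),
        # MEK inhibition: strong pErk reduction; pMEK feedback rises at 24 h
        e("Erk1/2_pT202/Y204", "selumetinib", 20, -2.0),
        e("Erk1/2_pT202/Y204", "selumetinib", 1440, -2.5),
        e("Mek1/2_pS217/S221", "selumetinib", 20, 0.5),
        e("Mek1/2_pS217/S221", "selumetinib", 1440, 1.5),
        e("S6_pS235/S236", "selumetinib", 1440, -1.0),
        e("cMyc", "selumetinib", 1440, -0.8),
    ]


def default_antigen_config(replicate_sd: float = 0.25) -> AntigenConfig:
    return AntigenConfig(
        antigens=list(ANTIGEN_CLASSES),
        replicate_sd=replicate_sd,
        effects=_default_effects(),
        sensitive=dict(DEFAULT_SENSITIVITY),
    )


def _phospho_site(antigen: str) -> str:
    return antigen.split("_p", 1)[1] if "_p" in antigen else ""


# Shared catalogue references for the single-antibody classes: the same
# physical antibody is used by all three sites, so it keeps one uid.
_BASE_REF = {a: f"CST-{1100 + i}" for i, a in enumerate(ANTIGEN_CLASSES)}
_BASE_REF["Erk1/2_pT202/Y204"] = "CST-4370"
# Her2 is probed by a different antibody at every site (plus extras below).
_HER2_REF = {"paris": "her2-P1", "heidelberg": "her2-H1", "edinburgh": "her2-E1"}

# Additional antibodies beyond one-per-class: panel sizes 29/31/27.
_EXTRA_PROBES: dict[str, list[tuple[str, str]]] = {
    "paris": [("Her2", "her2-P2"), ("Erk1/2_pT202/Y204", "CST-9101")],
    "heidelberg": [
        ("Her2", "her2-H2"),
        ("Erk1/2_pT202/Y204", "CST-9101"),
        ("EGFR", "egfr-H2"),
        ("S6_pS235/S236", "s6p-H2"),
    ],
    "edinburgh": [],
}

_PLATFORM_GAIN = {"paris": 1.0, "heidelberg": 1.1, "edinburgh": 0.9}
_PLATFORM_OFFSET = {"paris": 10.0, "heidelberg": 11.0, "edinburgh": 9.0}


def default_platforms(
    noise_sd: float = 0.15, noise_free: bool = False, loading_sd: float = 0.0
) -> list[PlatformConfig]:
    """The three default platform configurations (29/31/27-antibody panels).

    ``noise_free=True`` zeroes all spot noise and forces unit gain, giving
    the idealised setting in which downstream processing must recover the
    latent antigen matrix exactly.
    """
    platforms = []
    for pid in ("paris", "heidelberg", "edinburgh"):
        gain = 1.0 if noise_free else _PLATFORM_GAIN[pid]
        sd = 0.0 if noise_free else noise_sd
        panel = []
        for antigen in ANTIGEN_CLASSES:
            ref = _HER2_REF[pid] if antigen == "Her2" else _BASE_REF[antigen]
            targets: tuple[str, ...] = ()
            if pid == "edinburgh" and antigen == "Erk1/2":
                # declared against Erk1 only; synonym table merges it into Erk1/2
                targets = ("Erk1", "Erk1/2")
            panel.append(
                AntibodyProbe(
                    antibody_id=ref,
                    antigen=antigen,
                    supplier_ref=ref,
                    phospho_site=_phospho_site(antigen),
                    gain=gain,
                    offset=_PLATFORM_OFFSET[pid],
                    noise_sd=sd,
                    targets=targets,
                )
            )
        for antigen, ref in _EXTRA_PROBES[pid]:
            panel.append(
                AntibodyProbe(
                    antibody_id=ref,
                    antigen=antigen,
                    supplier_ref=ref,
                    phospho_site=_phospho_site(antigen),
                    gain=gain,
                    offset=_PLATFORM_OFFSET[pid],
                    noise_sd=sd,
                )
            )
        platforms.append(
            PlatformConfig(
                platform_id=pid,
                panel=panel,
                n_dilution_steps=4,
                n_technical_replicates=2,
                detection_floor=1.0,
                loading_sd=0.0 if noise_free else loading_sd,
            )
        )
    return platforms


def raw_annotation_table(platforms: list[PlatformConfig]) -> pd.DataFrame:
    """Raw (pre-classification) antibody annotation rows for a set of panels."""
    rows = []
    for p in platforms:
        for probe in p.panel:
            rows.append(
                {
                    "platform_id": p.platform_id,
                    "antibody_id": probe.antibody_id,
                    "targets": ";".join(probe.declared_targets()),
                    "supplier_ref": probe.supplier_ref,
                    "phospho_site": probe.phospho_site,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class SyntheticStudy:
    """A fully rendered synthetic study with its ground truth."""

    design: StudyDesign
    samples: list[SampleRecord]
    sample_table: pd.DataFrame
    latent: LatentAntigenMatrix
    platforms: list[PlatformConfig]
    renders: dict[str, PlatformRender]
    raw_annotations: pd.DataFrame
    seed: int


def simulate_study(
    seed: int,
    design: StudyDesign | None = None,
    antigen_config: AntigenConfig | None = None,
    platforms: list[PlatformConfig] | None = None,
) -> SyntheticStudy:
    """Generate the full default study (or a customised one) from one seed.

    When no antigen configuration is supplied, the default one is used
    with its drug effects and sensitivity flags restricted to the factors
    actually present in the design (so control-only or reduced designs
    work out of the box); an explicitly supplied configuration is
    validated strictly instead.
    """
    design = design or default_design()
    if antigen_config is None:
        antigen_config = default_antigen_config()
        cells = {c for c, _ in design.cell_lines}
        antigen_config.effects = [
            e
            for e in antigen_config.effects
            if e.treatment in design.treatments
            and (e.timepoint_min is None or e.timepoint_min in design.timepoints_min)
        ]
        antigen_config.sensitive = {
            t: frozenset(lines & cells)
            for t, lines in antigen_config.sensitive.items()
            if t in design.treatments
        }
    platforms = platforms if platforms is not None else default_platforms()
    samples = generate_design(design)
    latent = generate_latent_antigens(samples, antigen_config, derive_seed(seed, "latent"))
    renders = {
        p.platform_id: render_platform(latent, p, derive_seed(seed, f"platform:{p.platform_id}"))
        for p in platforms
    }
    return SyntheticStudy(
        design=design,
        samples=samples,
        sample_table=design_frame(samples),
        latent=latent,
        platforms=platforms,
        renders=renders,
        raw_annotations=raw_annotation_table(platforms),
        seed=seed,
    )


def control_subset(samples: list[SampleRecord], treatment: str = "DMSO",
                   timepoint_min: int = 20) -> list[SampleRecord]:
    """Vehicle-control samples at the early timepoint (the 'control dataset')."""
    return [s for s in samples if s.treatment == treatment and s.timepoint_min == timepoint_min]
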