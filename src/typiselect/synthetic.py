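"""Synthetic lymphoma fixtures: IHC case tables and slide-image stand-ins.

The generators emulate the structure of a diagnostic lymphoma archive so the
whole pipeline is testable without patient data:

* **IHC side** — each subtype has a core antibody panel; every case draws its
  core stains independently, always considers a small shared screening panel
  (CD20-class markers every workup touches), and occasionally adds rare
  extras.  A planted *atypical* case additionally borrows stains from another
  subtype's core — mimicking the workup of a case whose morphology suggested
  several subtypes, which is exactly the signature the typicality score is
  designed to pick up.  Defaults are calibrated to the aggregate shape of a
  real three-subtype archive: 87 candidate stains, 67/97/98 cases per
  subtype, about 9.8 stains per case, and roughly 35 stains surviving a
  used-by-at-least-10-cases filter.
* **Image side** — a slide stand-in is an elliptical "tissue" region on a
  white background; a sub-region (the planted foreground) carries a
  class-specific color texture while the rest is class-neutral.  An atypical
  slide's foreground is blended pixelwise toward another subtype's texture,
  so its appearance genuinely resembles the donor class — using it for
  training injects conflicting supervision instead of a learnable minority
  cue.  The ground-truth foreground mask is returned for
  attention-localization tests.

The same per-case atypical flag drives both generators, so grouping by IHC
typicality is coherently linked to image difficulty.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .ihc import CaseRecord, write_cases_csv

logger = logging.getLogger(__name__)

__all__ = [
    "IHCGeneratorConfig",
    "SlideGeneratorConfig",
    "SUBTYPE_NAMES",
    "gen_ihc_cases",
    "gen_slide_image",
    "gen_dataset",
]

SUBTYPE_NAMES = ("AITL", "DLBCL", "CHL")

# Realistic antibody names for the frequently used end of the vocabulary;
# the long tail is filled with generic marker names.
_STAIN_NAMES = [
    "CD20", "CD3", "CD5", "EBERISH", "CD30", "CD10", "BCL2", "BCL6", "CD15",
    "MUM1", "PAX5", "CD79a", "CD4", "CD8", "CD7", "CD56", "CD2", "CD21",
    "CD23", "CD25", "CCND1", "MIB1", "TIA1", "fascin", "FDC", "granzymeB",
    "perforin", "ALK1", "cmyc", "CD3epsilon", "CD43", "CD45", "EMA", "LMP1",
    "PD1", "CXCL13",
]


def _stain_name(i: int) -> str:
    return _STAIN_NAMES[i] if i < len(_STAIN_NAMES) else f"marker{i:03d}"


@dataclass
class IHCGeneratorConfig:
    """Configuration of the IHC staining-pattern generator.

    Core panels are contiguous index windows with overlap between adjacent
    subtypes (real panels share markers, e.g. CD30 between CHL and others).
    """

    K: int = 3
    L_raw: int = 87
    cases_per_subtype: tuple[int, ...] = (67, 97, 98)
    shared_panel: tuple[int, ...] = (0, 1, 2)
    shared_use_prob: float = 0.9
    core_panels: tuple[tuple[int, ...], ...] = (
        tuple(range(3, 16)),
        tuple(range(13, 26)),
        tuple(range(23, 36)),
    )
    core_use_prob: float = 0.42
    atypicality_rate: float = 0.3
    borrow_count: int = 5
    extra_rate: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.atypicality_rate <= 1:
            raise ValueError("atypicality_rate must be in [0, 1]")
        if not 0 <= self.core_use_prob <= 1 or not 0 <= self.shared_use_prob <= 1:
            raise ValueError("use probabilities must be in [0, 1]")
        if len(self.core_panels) != self.K or len(self.cases_per_subtype) != self.K:
            raise ValueError("core_panels and cases_per_subtype must have K entries")
        for p in self.core_panels:
            if len(p) == 0:
                raise ValueError("core panels must be nonempty")
            if min(p) < 0 or max(p) >= self.L_raw:
                raise ValueError("core panel indices must lie in [0, L_raw)")


@dataclass
class SlideGeneratorConfig:
    """Configuration of the slide-image stand-in generator."""

    image_size: int = 1024
    foreground_fraction: float = 0.4
    tissue_radius_fraction: float = 0.42
    class_colors: tuple[tuple[int, int, int], ...] = (
        (110, 50, 150),   # AITL-like: purple
        (160, 100, 50),   # DLBCL-like: brown
        (50, 80, 170),    # CHL-like: blue
    )
    base_color: tuple[int, int, int] = (220, 140, 180)  # eosin-pink stroma
    blob_radius: int = 6
    blob_density: float = 0.004  # blobs per foreground pixel
    texture_alpha: float = 0.75
    atypical_mixing: float = 0.7
    noise_sigma: float = 9.0
    stain_jitter: float = 0.18  # sd of per-slide multiplicative color variation
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.foreground_fraction < 1:
            raise ValueError("foreground_fraction must be in (0, 1)")
        if not 0 <= self.atypical_mixing <= 1:
            raise ValueError("atypical_mixing must be in [0, 1]")

    @classmethod
    def separable(cls, **kw) -> "SlideGeneratorConfig":
        """Preset without slide-level staining variation: class textures are
        cleanly separable by mean patch color (sanity bound for the MIL model)."""
        kw.setdefault("stain_jitter", 0.0)
        return cls(**kw)


def gen_ihc_cases(
    config: IHCGeneratorConfig | None = None,
) -> tuple[list[CaseRecord], np.ndarray]:
    """Generate the IHC case table and the ground-truth atypical flags.

    Each case: shared-panel stains at ``shared_use_prob``, its subtype's core
    stains independently at ``core_use_prob``, Poisson(``extra_rate``) rare
    extras from outside all panels, and — if flagged atypical — a uniformly
    chosen other subtype's core contributes ``borrow_count`` borrowed stains.
    Deterministic given ``config.seed``.
    """
    cfg = config or IHCGeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel_union = set(cfg.shared_panel)
    for p in cfg.core_panels:
        panel_union |= set(p)
    rare_pool = np.array(sorted(set(range(cfg.L_raw)) - panel_union))
    cases: list[CaseRecord] = []
    flags = []
    n_id = 0
    for k in range(cfg.K):
        core = np.array(cfg.core_panels[k])
        for _ in range(cfg.cases_per_subtype[k]):
            stains: set[int] = set()
            stains |= {s for s in cfg.shared_panel if rng.random() < cfg.shared_use_prob}
            stains |= {int(s) for s in core[rng.random(len(core)) < cfg.core_use_prob]}
            atypical = bool(rng.random() < cfg.atypicality_rate)
            others = [j for j in range(cfg.K) if j != k]
            if atypical and others:
                donor = others[int(rng.integers(len(others)))]
                borrowable = np.array(
                    sorted(set(cfg.core_panels[donor]) - set(core) - set(cfg.shared_panel))
                )
                n_borrow = min(cfg.borrow_count, len(borrowable))
                if n_borrow:
                    picked = rng.choice(len(borrowable), size=n_borrow, replace=False)
                    stains |= {int(borrowable[i]) for i in picked}
            n_extra = int(rng.poisson(cfg.extra_rate))
            if n_extra and len(rare_pool):
                picked = rng.choice(len(rare_pool), size=min(n_extra, len(rare_pool)), replace=False)
                stains |= {int(rare_pool[i]) for i in picked}
            if not stains:  # every workup uses at least the first screening stain
                stains = {int(cfg.shared_panel[0])}
            cases.append(
                CaseRecord(
                    case_id=f"case{n_id:04d}",
                    subtype=k,
                    stains=frozenset(_stain_name(s).lower() for s in stains),
                )
            )
            flags.append(atypical)
            n_id += 1
    flags = np.asarray(flags, dtype=bool)
    mean_stains = np.mean([len(c.stains) for c in cases])
    logger.info(
        "generated %d cases (%.2f stains/case, %.1f%% atypical)",
        len(cases), mean_stains, 100 * flags.mean(),
    )
    return cases, flags


def gen_slide_image(
    subtype: int,
    atypical: bool,
    config: SlideGeneratorConfig | None = None,
    seed: int | None = None,
    mix_subtype: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Generate one slide stand-in and its planted-foreground mask.

    Returns ``(image, foreground_mask)``: RGB uint8 and boolean.  The
    foreground (class-textured) disk occupies ``foreground_fraction`` of the
    tissue ellipse; an atypical slide's disk is painted with a color blended
    ``atypical_mixing`` of the way toward another subtype's texture.
    """
    cfg = config or SlideGeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    S = cfg.image_size
    yy, xx = np.mgrid[0:S, 0:S].astype(float)
    cy = cx = S / 2
    ry = cfg.tissue_radius_fraction * S * (1 + 0.1 * rng.uniform(-1, 1))
    rx = cfg.tissue_radius_fraction * S * (1 + 0.1 * rng.uniform(-1, 1))
    tissue = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0

    img = np.empty((S, S, 3), dtype=float)
    img[:] = (243, 242, 244)  # glass background
    img[tissue] = cfg.base_color

    # planted class-specific foreground: a disk inside the tissue ellipse
    tissue_area = float(tissue.sum())
    r_f = np.sqrt(cfg.foreground_fraction * tissue_area / np.pi)
    r_min = min(rx, ry)
    if r_f >= r_min:
        raise ValueError("foreground_fraction too large for the tissue region")
    max_off = max(r_min - r_f - 2, 0.0)
    ang = rng.uniform(0, 2 * np.pi)
    off = rng.uniform(0, 0.8 * max_off)
    fy, fx = cy + off * np.sin(ang), cx + off * np.cos(ang)
    fg = ((yy - fy) ** 2 + (xx - fx) ** 2 <= r_f**2) & tissue

    def paint(mask: np.ndarray, color: tuple[int, int, int]) -> None:
        col = np.asarray(color, dtype=float)
        img[mask] = (1 - cfg.texture_alpha) * img[mask] + cfg.texture_alpha * col
        # blob speckle for texture
        n_blobs = int(cfg.blob_density * mask.sum())
        ys, xs = np.nonzero(mask)
        if n_blobs and len(ys):
            pick = rng.integers(0, len(ys), size=n_blobs)
            for by, bx in zip(ys[pick], xs[pick]):
                r = cfg.blob_radius
                y0, y1 = max(by - r, 0), min(by + r + 1, S)
                x0, x1 = max(bx - r, 0), min(bx + r + 1, S)
                sub = (yy[y0:y1, x0:x1] - by) ** 2 + (xx[y0:y1, x0:x1] - bx) ** 2 <= r**2
                region = img[y0:y1, x0:x1]
                region[sub] = np.clip(col * rng.uniform(0.55, 0.8), 0, 255)
                img[y0:y1, x0:x1] = region

    # an atypical slide's lesion is a pixelwise blend toward another subtype's
    # texture: its appearance genuinely resembles the donor class, so using it
    # for training injects conflicting (noisy) supervision rather than a
    # learnable minority cue
    own = np.asarray(cfg.class_colors[subtype], dtype=float)
    col = own
    if atypical and cfg.atypical_mixing > 0:
        others = [j for j in range(len(cfg.class_colors)) if j != subtype]
        if others:
            donor = others[int(rng.integers(len(others)))] if mix_subtype is None else mix_subtype
            m = cfg.atypical_mixing
            col = (1 - m) * own + m * np.asarray(cfg.class_colors[donor], dtype=float)
    paint(fg, tuple(col))

    # slide-level staining variation: a multiplicative per-channel color cast,
    # applied to tissue only (the glass background stays near-white)
    if cfg.stain_jitter > 0:
        gain = np.exp(rng.normal(0, cfg.stain_jitter, size=3))
        img[tissue] = img[tissue] * gain[None, :]
    img += rng.normal(0, cfg.noise_sigma, img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return img, fg


def gen_dataset(
    ihc_config: IHCGeneratorConfig | None = None,
    slide_config: SlideGeneratorConfig | None = None,
    out_dir: str | Path | None = None,
    force: bool = False,
    write_slides: bool = True,
) -> dict:
    """Generate a coherent fixture: case table, flags, slides, masks, manifest.

    Returns the dataset in memory:
    ``{"cases", "flags", "slides": {case_id: {"image", "fg_mask", "label"}}}``.
    When ``out_dir`` is given the fixture is also written to disk
    (``cases.csv``, ``flags.csv``, ``slides/*.png``, ``masks/*.png``,
    ``manifest.json``); regeneration from the same configs is byte-identical.
    """
    ihc_cfg = ihc_config or IHCGeneratorConfig()
    slide_cfg = slide_config or SlideGeneratorConfig()
    cases, flags = gen_ihc_cases(ihc_cfg)
    slides: dict[str, dict] = {}
    if write_slides:
        rng = np.random.default_rng(slide_cfg.seed)
        for c, atypical in zip(cases, flags):
            sseed = int(rng.integers(2**31 - 1))
            img, fg = gen_slide_image(c.subtype, bool(atypical), slide_cfg, seed=sseed)
            c.slide_ref = f"slides/{c.case_id}.png"
            slides[c.case_id] = {"image": img, "fg_mask": fg, "label": c.subtype}
    data = {"cases": cases, "flags": flags, "slides": slides}

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        if out.exists() and any(out.iterdir()) and not force:
            raise FileExistsError(f"{out} is not empty; pass force=True to overwrite")
        (out / "slides").mkdir(parents=True, exist_ok=True)
        (out / "masks").mkdir(parents=True, exist_ok=True)
        write_cases_csv(cases, out / "cases.csv", subtype_names=SUBTYPE_NAMES[: ihc_cfg.K])
        flag_lines = ["case_id,atypical"] + [
            f"{c.case_id},{int(f)}" for c, f in zip(cases, flags)
        ]
        (out / "flags.csv").write_text("\n".join(flag_lines) + "\n")
        for cid, d in slides.items():
            iio.imwrite(out / "slides" / f"{cid}.png", d["image"])
            iio.imwrite(out / "masks" / f"{cid}.png", (d["fg_mask"] * 255).astype(np.uint8))
        manifest = {
            "ihc_config": asdict(ihc_cfg),
            "slide_config": asdict(slide_cfg),
            "n_cases": len(cases),
            "subtype_names": list(SUBTYPE_NAMES[: ihc_cfg.K]),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return data
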