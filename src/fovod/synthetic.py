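"""Synthetic detection scenes and orientation pop-out images.

Scenes composite high-edge-energy glyphs (two shape families, two
viewpoints each) onto a 1/f-noise background, with bounding boxes tight
to the rendered glyph mask.  Object scale and placement emulate the
statistics of common detection benchmarks: mean box area around 0.2 of
the image area and a central position bias.  Everything is deterministic
given the seed.  Pop-out images carry an orientation-contrast patch on
an oriented-texture background for the saliency experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
from lxml import etree
from skimage.draw import polygon

CLASSES = ("wedge", "cross")


class PlacementError(RuntimeError):
    """An object could not be placed inside the image."""


@dataclass
class SceneSpec:
    """Study conditions of the synthetic scene generator."""

    size: tuple[int, int] = (320, 320)          # (H, W)
    classes: tuple = CLASSES
    # probability of 0, 1, 2, ... objects per scene
    objects_per_image: tuple = (0.25, 0.35, 0.40)
    norm_area_mean: float = 0.2                 # mean box area / image area
    area_sigma: float = 0.15                    # lognormal scale jitter
    center_bias: float = 0.25                   # placement std, fraction of size
    background_amplitude: float = 0.07          # 1/f noise amplitude
    glyph_intensity: float = 1.0
    background_level: float = 0.45

    def __post_init__(self):
        if abs(sum(self.objects_per_image) - 1) > 1e-9:
            raise ValueError("objects_per_image must sum to 1")


def one_over_f_noise(shape, rng, amplitude=1.0, exponent=1.0):
    """Zero-mean 1/f^exponent spatial noise, unit-free."""
    H, W = shape
    fy = np.fft.fftfreq(H)[:, None]
    fx = np.fft.fftfreq(W)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0
    spec = (rng.standard_normal((H, W)) + 1j * rng.standard_normal((H, W)))
    spec /= f ** exponent
    noise = np.real(np.fft.ifft2(spec))
    noise -= noise.mean()
    s = noise.std()
    return amplitude * noise / (s if s > 0 else 1.0)


def glyph_mask(class_name: str, viewpoint: int, w: int, h: int) -> np.ndarray:
    """Boolean mask of a glyph rendered into a (h, w) window.

    ``wedge``: a solid triangle pointing up (viewpoint 0) or right (1).
    ``cross``: a plus sign (viewpoint 0) or a diagonal X (1).
    """
    mask = np.zeros((h, w), dtype=bool)
    if class_name == "wedge":
        if viewpoint == 0:
            pts = [(h - 1, 0), (h - 1, w - 1), (0, (w - 1) / 2)]
        else:
            pts = [(0, 0), (h - 1, 0), ((h - 1) / 2, w - 1)]
        rr, cc = polygon([p[0] for p in pts], [p[1] for p in pts], mask.shape)
        mask[rr, cc] = True
    elif class_name == "cross":
        if viewpoint == 0:
            bw = max(2, int(round(0.3 * min(w, h))))
            y0 = (h - bw) // 2
            x0 = (w - bw) // 2
            mask[y0:y0 + bw, :] = True
            mask[:, x0:x0 + bw] = True
        else:
            t = max(1.0, 0.18 * min(w, h))
            yy, xx = np.mgrid[0:h, 0:w]
            u = yy / (h - 1) - xx / (w - 1)
            v = yy / (h - 1) + xx / (w - 1) - 1
            scale = min(w, h)
            mask[np.abs(u) * scale / 2 < t / 2] = True
            mask[np.abs(v) * scale / 2 < t / 2] = True
    else:
        raise ValueError(f"unknown glyph class {class_name!r}")
    return mask


# per (class, viewpoint) aspect ratio w/h, so the two viewpoints of a
# class land in different template clusters
_ASPECT = {("wedge", 0): 1.4, ("wedge", 1): 1 / 1.4,
           ("cross", 0): 1.35, ("cross", 1): 1 / 1.35}


def generate_scene(spec: SceneSpec, rng: np.random.Generator):
    """Render one scene; returns (image in [0, 1], annotations).

    Annotations are ``(class_name, (w, h, x, y))`` with the box tight to
    the glyph mask extent.
    """
    H, W = spec.size
    image = spec.background_level + one_over_f_noise(
        (H, W), rng, spec.background_amplitude)
    n_obj = rng.choice(len(spec.objects_per_image), p=spec.objects_per_image)
    annotations = []
    placed_boxes = []
    for _ in range(n_obj):
        cls = str(rng.choice(spec.classes))
        vp = int(rng.integers(2))
        area = spec.norm_area_mean * H * W * float(
            rng.lognormal(0.0, spec.area_sigma))
        aspect = _ASPECT.get((cls, vp), 1.0)
        gw = int(round(np.sqrt(area * aspect)))
        gh = int(round(np.sqrt(area / aspect)))
        gw = min(gw, W - 2)
        gh = min(gh, H - 2)
        if gw < 8 or gh < 8:
            raise PlacementError("object too small to render")
        for attempt in range(20):
            cx = rng.normal(W / 2, spec.center_bias * W)
            cy = rng.normal(H / 2, spec.center_bias * H)
            x = int(round(cx - gw / 2))
            y = int(round(cy - gh / 2))
            if x < 0 or y < 0 or x + gw > W or y + gh > H:
                continue
            cand = (gw, gh, x, y)
            from .evaluation import iou
            if any(iou(cand, pb) > 0.3 for pb in placed_boxes):
                continue
            break
        else:
            raise PlacementError("could not place object after 20 attempts")
        mask = glyph_mask(cls, vp, gw, gh)
        sub = image[y:y + gh, x:x + gw]
        sub[mask] = spec.glyph_intensity + 0.03 * rng.standard_normal()
        rows = np.nonzero(mask.any(axis=1))[0]
        cols = np.nonzero(mask.any(axis=0))[0]
        box = (int(cols[-1] - cols[0] + 1), int(rows[-1] - rows[0] + 1),
               int(x + cols[0]), int(y + rows[0]))
        annotations.append((cls, box))
        placed_boxes.append(box)
    return np.clip(image, 0, 1), annotations


@dataclass
class SceneRecord:
    id: str
    image: np.ndarray
    annotations: list


def generate_dataset(spec: SceneSpec, n_train: int, n_test: int, seed: int
                     ) -> tuple[list[SceneRecord], list[SceneRecord]]:
    """Two disjointly seeded annotated splits."""
    splits = []
    for split_idx, n in ((0, n_train), (1, n_test)):
        records = []
        for i in range(n):
            rng = np.random.default_rng([seed, split_idx, i])
            img, ann = generate_scene(spec, rng)
            records.append(SceneRecord(
                id=f"{'train' if split_idx == 0 else 'test'}_{i:05d}",
                image=img, annotations=ann))
        splits.append(records)
    return splits[0], splits[1]


def generate_popout_image(size, background_orientation: float,
                          target_orientation: float, target_position,
                          rng: np.random.Generator, wavelength: float = 8.0,
                          patch_radius_px: float = 24.0,
                          noise: float = 0.02) -> np.ndarray:
    """Oriented-texture background with one orientation-contrast patch.

    Orientations are in degrees; the patch is blended in with a
    raised-cosine window centered at ``target_position`` (x, y) px.
    """
    H, W = size
    yy, xx = np.mgrid[0:H, 0:W]

    def grating(theta_deg, phase):
        t = np.deg2rad(theta_deg)
        u = xx * np.cos(t) + yy * np.sin(t)
        return np.sin(2 * np.pi * u / wavelength + phase)

    phase = rng.uniform(0, 2 * np.pi)       # shared: the patch differs
    bg = grating(background_orientation, phase)  # from the background in
    tg = grating(target_orientation, phase)      # orientation only
    tx, ty = target_position
    r = np.hypot(xx - tx, yy - ty)
    win = np.where(r <= patch_radius_px,
                   0.5 * (1 + np.cos(np.pi * np.minimum(r / patch_radius_px,
                                                        1.0))), 0.0)
    img = 0.5 + 0.25 * ((1 - win) * bg + win * tg)
    img = img + noise * rng.standard_normal((H, W))
    return np.clip(img, 0, 1)


# ---------------------------------------------------------------------------
# annotation I/O (VOC XML dialect and a compact CSV)


def write_voc_xml(path, image_id: str, size, annotations):
    """Write one image's annotations in the VOC XML dialect.

    Boxes are stored as 1-based inclusive xmin/ymin/xmax/ymax, converted
    from the package's (w, h, x, y) half-open convention.
    """
    H, W = size
    root = etree.Element("annotation")
    etree.SubElement(root, "filename").text = f"{image_id}.png"
    sz = etree.SubElement(root, "size")
    etree.SubElement(sz, "width").text = str(W)
    etree.SubElement(sz, "height").text = str(H)
    etree.SubElement(sz, "depth").text = "1"
    for cls, (w, h, x, y) in annotations:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = cls
        etree.SubElement(obj, "difficult").text = "0"
        bb = etree.SubElement(obj, "bndbox")
        etree.SubElement(bb, "xmin").text = str(int(x) + 1)
        etree.SubElement(bb, "ymin").text = str(int(y) + 1)
        etree.SubElement(bb, "xmax").text = str(int(x + w))
        etree.SubElement(bb, "ymax").text = str(int(y + h))
    Path(path).write_bytes(etree.tostring(root, pretty_print=True))


def read_voc_xml(path):
    """Read annotations back as ``(class, (w, h, x, y))`` tuples."""
    root = etree.parse(str(path)).getroot()
    out = []
    for obj in root.findall("object"):
        cls = obj.findtext("name")
        bb = obj.find("bndbox")
        x1 = int(bb.findtext("xmin")) - 1
        y1 = int(bb.findtext("ymin")) - 1
        x2 = int(bb.findtext("xmax"))
        y2 = int(bb.findtext("ymax"))
        out.append((cls, (x2 - x1, y2 - y1, x1, y1)))
    return out


def write_dataset(records, out_dir):
    """VOC-style folder layout: JPEGImages/ + Annotations/ (+ a CSV)."""
    import imageio.v3 as iio

    out = Path(out_dir)
    (out / "JPEGImages").mkdir(parents=True, exist_ok=True)
    (out / "Annotations").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        iio.imwrite(out / "JPEGImages" / f"{rec.id}.png",
                    (rec.image * 255).astype(np.uint8))
        write_voc_xml(out / "Annotations" / f"{rec.id}.xml", rec.id,
                      rec.image.shape[:2], rec.annotations)
        for cls, (w, h, x, y) in rec.annotations:
            rows.append(f"{rec.id},{cls},{w},{h},{x},{y}")
    (out / "annotations.csv").write_text(
        "image_id,class,w,h,x,y\n" + "".join(r + "\n" for r in rows))


def read_dataset(in_dir) -> list[SceneRecord]:
    import imageio.v3 as iio

    root = Path(in_dir)
    records = []
    for xml in sorted((root / "Annotations").glob("*.xml")):
        image_id = xml.stem
        img = iio.imread(root / "JPEGImages" / f"{image_id}.png") / 255.0
        records.append(SceneRecord(id=image_id, image=img,
                                   annotations=read_voc_xml(xml)))
    return records
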