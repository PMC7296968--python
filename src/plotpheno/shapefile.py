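"""Minimal ESRI Shapefile polygon layer reader/writer (.shp/.shx/.dbf/.prj).

Covers exactly what plot-boundary layers need: 2-D polygon records (shape
type 5) with string attributes in a dBase III table. Exterior rings are
written clockwise, holes counter-clockwise, per the ESRI white paper; the
reader classifies rings by winding order and assigns holes to the exterior
that contains them.
"""

from __future__ import annotations

import os
import struct
from pathlib import Path

from shapely.geometry import Polygon
from shapely.geometry.polygon import orient

from .errors import VectorIOError
from .geo import PlotPolygon

_SHAPE_POLYGON = 5
_FILE_CODE = 9994
_VERSION = 1000


def _ring_coords(ring) -> list[tuple[float, float]]:
    return [(float(x), float(y)) for x, y in ring.coords]


def _signed_area(pts) -> float:
    area = 0.0
    for (x0, y0), (x1, y1) in zip(pts, pts[1:]):
        area += x0 * y1 - x1 * y0
    return area / 2.0


def _polygon_parts(geom: Polygon) -> list[list[tuple[float, float]]]:
    # ESRI convention: exterior clockwise (negative signed area), holes CCW
    g = orient(geom, sign=-1.0)
    parts = [_ring_coords(g.exterior)]
    parts.extend(_ring_coords(hole) for hole in g.interiors)
    return parts


def write_polygons(plots: list[PlotPolygon], path: str | os.PathLike,
                   id_field: str = "plot_id", crs: str | None = None) -> None:
    """Write a polygon layer; attributes become string (C) dBase fields."""
    base = Path(path).with_suffix("")
    if not plots:
        raise VectorIOError("no polygons to write")

    records = []
    for p in plots:
        parts = _polygon_parts(p.geometry)
        points = [pt for ring in parts for pt in ring]
        offsets, n = [], 0
        for ring in parts:
            offsets.append(n)
            n += len(ring)
        minx, miny, maxx, maxy = p.geometry.bounds
        content = struct.pack("<i", _SHAPE_POLYGON)
        content += struct.pack("<4d", minx, miny, maxx, maxy)
        content += struct.pack("<2i", len(parts), len(points))
        content += struct.pack(f"<{len(parts)}i", *offsets)
        content += b"".join(struct.pack("<2d", x, y) for x, y in points)
        records.append(content)

    gminx = min(p.geometry.bounds[0] for p in plots)
    gminy = min(p.geometry.bounds[1] for p in plots)
    gmaxx = max(p.geometry.bounds[2] for p in plots)
    gmaxy = max(p.geometry.bounds[3] for p in plots)

    def header(total_words: int) -> bytes:
        h = struct.pack(">7i", _FILE_CODE, 0, 0, 0, 0, 0, total_words)
        h += struct.pack("<2i", _VERSION, _SHAPE_POLYGON)
        h += struct.pack("<8d", gminx, gminy, gmaxx, gmaxy, 0, 0, 0, 0)
        return h

    shp_words = 50 + sum(4 + len(c) // 2 for c in records)
    with open(base.with_suffix(".shp"), "wb") as shp, \
            open(base.with_suffix(".shx"), "wb") as shx:
        shp.write(header(shp_words))
        shx.write(header(50 + 4 * len(records)))
        offset = 50
        for i, content in enumerate(records, start=1):
            words = len(content) // 2
            shx.write(struct.pack(">2i", offset, words))
            shp.write(struct.pack(">2i", i, words))
            shp.write(content)
            offset += 4 + words

    _write_dbf(plots, base.with_suffix(".dbf"), id_field)

    if crs is not None:
        # placeholder WKT carrying the EPSG authority code
        code = str(crs).split(":")[-1]
        base.with_suffix(".prj").write_text(
            f'PROJCS["{crs}",AUTHORITY["EPSG","{code}"]]')


def _write_dbf(plots: list[PlotPolygon], path: Path, id_field: str) -> None:
    attr_keys: list[str] = []
    for p in plots:
        for k in p.attributes:
            if k not in attr_keys:
                attr_keys.append(k)
    fields = [(id_field, 32)] + [(k, 32) for k in attr_keys]

    header_size = 32 + 32 * len(fields) + 1
    record_size = 1 + sum(w for _, w in fields)
    with open(path, "wb") as f:
        f.write(struct.pack("<B3BIHH20x", 0x03, 95, 7, 26,
                            len(plots), header_size, record_size))
        for name, width in fields:
            f.write(struct.pack("<11sc4xBB14x",
                                name.encode("ascii")[:10], b"C", width, 0))
        f.write(b"\x0d")
        for p in plots:
            f.write(b" ")
            values = [p.plot_id] + [str(p.attributes.get(k, "")) for k in attr_keys]
            for (name, width), v in zip(fields, values):
                f.write(v.encode("utf-8")[:width].ljust(width))
        f.write(b"\x1a")


def load_polygons(path: str | os.PathLike, id_field: str = "plot_id") -> list[PlotPolygon]:
    """Load a polygon shapefile layer; one PlotPolygon per feature.

    Errors on non-polygon layers, a missing ``id_field`` attribute, or
    duplicate ids.
    """
    base = Path(path).with_suffix("")
    shp_path = base.with_suffix(".shp")
    if not shp_path.exists():
        raise VectorIOError(f"no such shapefile: {shp_path}")
    geoms = _read_shp(shp_path)
    table = _read_dbf(base.with_suffix(".dbf"))
    if len(table) != len(geoms):
        raise VectorIOError(".shp and .dbf record counts differ")
    if table and id_field not in table[0]:
        raise VectorIOError(f"attribute {id_field!r} not present in .dbf")

    plots, seen = [], set()
    for geom, attrs in zip(geoms, table):
        pid = attrs.pop(id_field)
        if pid in seen:
            raise VectorIOError(f"duplicate plot id {pid!r}")
        seen.add(pid)
        plots.append(PlotPolygon(plot_id=pid, geometry=geom, attributes=attrs))
    return plots


def _read_shp(path: Path) -> list[Polygon]:
    data = path.read_bytes()
    (shape_type,) = struct.unpack_from("<i", data, 32)
    if shape_type != _SHAPE_POLYGON:
        raise VectorIOError(f"not a polygon layer (shape type {shape_type})")
    geoms, pos = [], 100
    while pos < len(data):
        _, words = struct.unpack_from(">2i", data, pos)
        pos += 8
        rec_type = struct.unpack_from("<i", data, pos)[0]
        if rec_type != _SHAPE_POLYGON:
            raise VectorIOError(f"record with non-polygon shape type {rec_type}")
        nparts, npoints = struct.unpack_from("<2i", data, pos + 36)
        parts = struct.unpack_from(f"<{nparts}i", data, pos + 44)
        pts_off = pos + 44 + 4 * nparts
        flat = struct.unpack_from(f"<{2 * npoints}d", data, pts_off)
        pts = list(zip(flat[0::2], flat[1::2]))
        rings = [pts[parts[i]:(parts[i + 1] if i + 1 < nparts else npoints)]
                 for i in range(nparts)]
        geoms.append(_assemble(rings))
        pos += 2 * words
    return geoms


def _assemble(rings) -> Polygon:
    exteriors = [r for r in rings if _signed_area(r) <= 0]  # clockwise
    holes = [r for r in rings if _signed_area(r) > 0]
    if len(exteriors) != 1:
        raise VectorIOError("multi-part polygons are not supported for plots")
    return Polygon(exteriors[0], holes)


def _read_dbf(path: Path) -> list[dict]:
    if not path.exists():
        raise VectorIOError(f"missing attribute table: {path}")
    data = path.read_bytes()
    n_records, header_size, record_size = struct.unpack_from("<IHH", data, 4)
    fields, pos = [], 32
    while data[pos] != 0x0D:
        name = data[pos:pos + 11].split(b"\x00")[0].decode("ascii")
        width = data[pos + 16]
        fields.append((name, width))
        pos += 32
    out, pos = [], header_size
    for _ in range(n_records):
        rec, off = {}, pos + 1  # skip deletion flag
        for name, width in fields:
            rec[name] = data[off:off + width].decode("utf-8").strip()
            off += width
        out.append(rec)
        pos += record_size
    return out
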