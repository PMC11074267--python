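"""MRC2014 volume I/O and validation.

The MRC2014 format stores a 3D scalar field as a 1024-byte header, an
optional extended header, and a data section whose fastest-varying axis is
the header's ``mapc`` axis.  All volumes in this package are normalized on
read so that the in-memory array is indexed ``(i, j, k) = (z, y, x)``;
files are written with the identity axis mapping ``mapc, mapr, maps =
1, 2, 3``.

Voxel sizes and origins are in Angstrom, following the convention of
deposited cryo-EM maps: ``origin`` gives the position of the center of
voxel ``(0, 0, 0)``.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

HEADER_BYTES = 1024
LABEL_BYTES = 80
N_LABELS = 10

#: dtype for each supported MRC mode
MODE_DTYPES = {
    0: np.dtype(np.int8),
    1: np.dtype(np.int16),
    2: np.dtype(np.float32),
    4: np.dtype(np.complex64),
    6: np.dtype(np.uint16),
    12: np.dtype(np.float16),
}

#: accepted machine-stamp prefixes (little-endian x2, VAX, big-endian)
MACHINE_STAMPS = (b"\x44\x44\x00\x00", b"\x44\x41\x00\x00", b"\x11\x11\x00\x00")

VALID_NVERSIONS = (20140, 20141)

#: relative tolerance for the header-statistics check, scaled by the data range
STATS_RTOL = 1e-4


class MrcFormatError(ValueError):
    """Header is not parseable as MRC2014."""


class MrcSizeError(ValueError):
    """Data section on disk is shorter than the header implies."""


@dataclass
class DensityGrid:
    """A 3D scalar field on a regular grid.

    Attributes
    ----------
    data : ndarray, shape (nz, ny, nx)
        Volume indexed ``(i, j, k) = (z, y, x)``.
    voxel_size : tuple of float
        Voxel edge lengths ``(x, y, z)`` in Angstrom.
    origin : tuple of float
        Position ``(x, y, z)`` in Angstrom of voxel ``(0, 0, 0)``.
    mode : int
        MRC storage mode the data came from / will be written as.
    labels : list of str
        Free-text header labels.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mode: int = 2
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("grid data must be 3D with all dimensions >= 1")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        """Grid shape as (nz, ny, nx)."""
        return self.data.shape

    def extent(self) -> tuple[float, float, float]:
        """Physical extent (x, y, z) in Angstrom covered by the grid."""
        nz, ny, nx = self.data.shape
        vx, vy, vz = self.voxel_size
        return (nx * vx, ny * vy, nz * vz)


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


@dataclass
class MrcValidationReport:
    """Outcome of the per-field MRC2014 compliance checks."""

    checks: dict[str, CheckResult]

    @property
    def overall(self) -> bool:
        return all(c.passed for c in self.checks.values())

    def failures(self) -> list[CheckResult]:
        return [c for c in self.checks.values() if not c.passed]

    def to_dict(self) -> dict:
        return {
            "overall": self.overall,
            "checks": {
                k: {"passed": c.passed, "detail": c.detail}
                for k, c in self.checks.items()
            },
        }


def _parse_header(raw: bytes) -> dict:
    if len(raw) < HEADER_BYTES:
        raise MrcFormatError("file shorter than the 1024-byte MRC header")
    i32 = np.frombuffer(raw, dtype="<i4", count=256)
    f32 = np.frombuffer(raw, dtype="<f4", count=256)
    h = {
        "nx": int(i32[0]),
        "ny": int(i32[1]),
        "nz": int(i32[2]),
        "mode": int(i32[3]),
        "nxstart": int(i32[4]),
        "nystart": int(i32[5]),
        "nzstart": int(i32[6]),
        "mx": int(i32[7]),
        "my": int(i32[8]),
        "mz": int(i32[9]),
        "cella": tuple(float(v) for v in f32[10:13]),
        "cellb": tuple(float(v) for v in f32[13:16]),
        "mapc": int(i32[16]),
        "mapr": int(i32[17]),
        "maps": int(i32[18]),
        "dmin": float(f32[19]),
        "dmax": float(f32[20]),
        "dmean": float(f32[21]),
        "ispg": int(i32[22]),
        "nsymbt": int(i32[23]),
        "exttyp": raw[104:108].decode("ascii", errors="replace"),
        "nversion": int(i32[27]),
        "origin": tuple(float(v) for v in f32[49:52]),
        "map_id": raw[208:212].decode("ascii", errors="replace"),
        "machst": raw[212:216],
        "rms": float(f32[54]),
        "nlabl": int(i32[55]),
        "labels": [
            raw[224 + i * LABEL_BYTES : 224 + (i + 1) * LABEL_BYTES]
            .decode("ascii", errors="replace")
            for i in range(N_LABELS)
        ],
    }
    return h


def read_mrc(path) -> DensityGrid:
    """Read an MRC2014 volume, normalizing the axis order to (z, y, x).

    Raises
    ------
    MrcFormatError
        If the header is unparseable or the mode is unsupported.
    MrcSizeError
        If the data section is shorter than the header implies.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    h = _parse_header(raw)
    if "MAP" not in h["map_id"]:
        raise MrcFormatError(f"missing MAP id string in header of {path!r}")
    if h["mode"] not in MODE_DTYPES:
        raise MrcFormatError(f"unsupported MRC mode {h['mode']}")
    dtype = MODE_DTYPES[h["mode"]]
    n_items = h["nx"] * h["ny"] * h["nz"]
    start = HEADER_BYTES + max(h["nsymbt"], 0)
    expected = start + n_items * dtype.itemsize
    if len(raw) < expected:
        raise MrcSizeError(
            f"data section truncated: file has {len(raw)} bytes, "
            f"header implies {expected}"
        )
    data = np.frombuffer(raw, dtype=dtype.newbyteorder("<"), count=n_items,
                         offset=start)
    # file layout is (sections, rows, columns)
    data = data.reshape(h["nz"], h["ny"], h["nx"])

    mapping = (h["mapc"], h["mapr"], h["maps"])
    if sorted(mapping) != [1, 2, 3]:
        raise MrcFormatError(f"axis mapping {mapping} is not a permutation of 1,2,3")
    # spatial axis (1=x, 2=y, 3=z) carried by each file dimension (sec,row,col)
    file_dim_axis = (h["maps"], h["mapr"], h["mapc"])
    # transpose so dims are ordered (z, y, x) = axes (3, 2, 1)
    order = tuple(file_dim_axis.index(a) for a in (3, 2, 1))
    data = np.ascontiguousarray(np.transpose(data, order))

    # sampling counts and starts per spatial axis x,y,z
    m = (h["mx"], h["my"], h["mz"])
    voxel = tuple(
        h["cella"][a] / m[a] if m[a] > 0 else 0.0 for a in range(3)
    )
    origin = h["origin"]
    if origin == (0.0, 0.0, 0.0):
        # legacy dialect: nstart offsets in voxel units along (col,row,sec)
        nstart_axis = [0, 0, 0]
        for n, a in zip((h["nxstart"], h["nystart"], h["nzstart"]),
                        (h["mapc"], h["mapr"], h["maps"])):
            nstart_axis[a - 1] = n
        origin = tuple(nstart_axis[a] * voxel[a] for a in range(3))

    labels = [lbl.rstrip("\x00 ") for lbl in h["labels"][: max(h["nlabl"], 0)]
              if lbl.strip("\x00 ")]
    return DensityGrid(data=data, voxel_size=voxel, origin=origin,
                       mode=h["mode"], labels=labels)


def write_mrc(grid: DensityGrid, path) -> None:
    """Write a grid as an MRC2014 file (mode 2, identity axis mapping).

    Header statistics are recomputed from the data; the version field is
    set to 20140 and the machine stamp to the little-endian pattern.

    Raises
    ------
    ValueError
        If the data contains non-finite values.
    """
    data = np.asarray(grid.data, dtype=np.float32)
    if not np.all(np.isfinite(data)):
        raise ValueError("grid data contains non-finite values")
    nz, ny, nx = data.shape
    vx, vy, vz = grid.voxel_size

    header = bytearray(HEADER_BYTES)
    i32 = np.zeros(256, dtype="<i4")
    f32 = np.zeros(256, dtype="<f4")

    i32[0:3] = (nx, ny, nz)
    i32[3] = 2  # mode: 32-bit real
    i32[4:7] = (0, 0, 0)
    i32[7:10] = (nx, ny, nz)
    f32[10:13] = (nx * vx, ny * vy, nz * vz)
    f32[13:16] = (90.0, 90.0, 90.0)
    i32[16:19] = (1, 2, 3)
    f32[19] = float(data.min())
    f32[20] = float(data.max())
    f32[21] = float(data.mean(dtype=np.float64))
    i32[22] = 1  # spacegroup P1: single volume
    i32[23] = 0  # no extended header
    i32[27] = 20140
    f32[49:52] = grid.origin
    f32[54] = float(data.std(dtype=np.float64))

    labels = list(grid.labels) or ["mapforge"]
    labels = labels[:N_LABELS]
    i32[55] = len(labels)

    ib = i32.tobytes()
    fb = f32.tobytes()
    # integer fields
    for sl in (slice(0, 40), slice(64, 76), slice(88, 96), slice(108, 112),
               slice(220, 224)):
        header[sl] = ib[sl]
    # float fields
    for sl in (slice(40, 64), slice(76, 88), slice(196, 208), slice(216, 220)):
        header[sl] = fb[sl]
    header[104:108] = b"\x00\x00\x00\x00"  # exttyp unused (nsymbt = 0)
    header[208:212] = b"MAP "
    header[212:216] = MACHINE_STAMPS[0]
    for i, lbl in enumerate(labels):
        enc = lbl.encode("ascii", errors="replace")[:LABEL_BYTES]
        header[224 + i * LABEL_BYTES : 224 + i * LABEL_BYTES + len(enc)] = enc

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(data.tobytes())


def _check(checks: dict, name: str, passed: bool, detail: str = "") -> None:
    checks[name] = CheckResult(name=name, passed=bool(passed), detail=detail)


def validate_mrc(path) -> MrcValidationReport:
    """Run the MRC2014 compliance checks on a file.

    Individual failures are recorded in the report rather than raised; only
    an unopenable file raises. The checks cover: the MAP id string, the
    machine stamp, the storage mode, map/cell dimensions, the axis mapping,
    volume-stack divisibility, header labels, the format version, the
    extended-header type, header statistics, and the on-disk file size.
    """
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < HEADER_BYTES:
        checks: dict[str, CheckResult] = {}
        _check(checks, "file_size", False,
               f"file is {len(raw)} bytes, smaller than the 1024-byte header")
        return MrcValidationReport(checks=checks)

    h = _parse_header(raw)
    checks = {}

    _check(checks, "map_id", "MAP" in h["map_id"],
           f"map field is {h['map_id']!r}")
    _check(checks, "machine_stamp", bytes(h["machst"]) in MACHINE_STAMPS,
           f"machine stamp is {bytes(h['machst']).hex()}")
    _check(checks, "mode", h["mode"] in MODE_DTYPES,
           f"mode is {h['mode']}")
    dims = (h["nx"], h["ny"], h["nz"], h["mx"], h["my"], h["mz"]) + h["cella"]
    _check(checks, "dimensions", all(d > 0 for d in dims),
           f"nx,ny,nz,mx,my,mz,cella = {dims}")
    _check(checks, "axis_mapping",
           sorted((h["mapc"], h["mapr"], h["maps"])) == [1, 2, 3],
           f"mapc,mapr,maps = {(h['mapc'], h['mapr'], h['maps'])}")

    if 401 <= h["ispg"] <= 630:
        ok = h["mz"] > 0 and h["nz"] % h["mz"] == 0
        _check(checks, "volume_stack", ok,
               f"volume stack with nz={h['nz']}, mz={h['mz']}")
    else:
        _check(checks, "volume_stack", True, "not a volume stack")

    nlabl_ok = 0 <= h["nlabl"] <= N_LABELS
    labels_in_use_first = all(
        not h["labels"][i].strip("\x00 ")
        for i in range(max(h["nlabl"], 0), N_LABELS)
    )
    _check(checks, "labels", nlabl_ok and labels_in_use_first,
           f"nlabl = {h['nlabl']}")
    _check(checks, "nversion", h["nversion"] in VALID_NVERSIONS,
           f"nversion = {h['nversion']}")

    if h["nsymbt"] > 0:
        _check(checks, "exttyp", h["exttyp"].strip("\x00 ") != "",
               f"extended header of {h['nsymbt']} bytes, exttyp = {h['exttyp']!r}")
    else:
        _check(checks, "exttyp", True, "no extended header")

    dtype = MODE_DTYPES.get(h["mode"])
    if dtype is None:
        _check(checks, "statistics", False, "statistics unverifiable: bad mode")
        _check(checks, "file_size", False, "file size unverifiable: bad mode")
        return MrcValidationReport(checks=checks)

    n_items = h["nx"] * h["ny"] * h["nz"]
    expected = HEADER_BYTES + max(h["nsymbt"], 0) + n_items * dtype.itemsize
    _check(checks, "file_size", len(raw) == expected,
           f"file is {len(raw)} bytes, header implies {expected}")

    if len(raw) >= expected and n_items > 0 and h["mode"] != 4:
        data = np.frombuffer(raw, dtype=dtype.newbyteorder("<"), count=n_items,
                             offset=HEADER_BYTES + max(h["nsymbt"], 0))
        data = data.astype(np.float64)
        dmin, dmax = data.min(), data.max()
        tol = STATS_RTOL * max(dmax - dmin, 1.0)
        # undetermined markers per the standard: dmax < dmin, dmean below
        # both, rms < 0
        minmax_ok = (h["dmax"] < h["dmin"]) or (
            abs(h["dmin"] - dmin) <= tol and abs(h["dmax"] - dmax) <= tol
        )
        mean_ok = (h["dmean"] < min(h["dmin"], h["dmax"])) or (
            abs(h["dmean"] - data.mean()) <= tol
        )
        rms_ok = (h["rms"] < 0) or (abs(h["rms"] - data.std()) <= tol)
        _check(checks, "statistics", minmax_ok and mean_ok and rms_ok,
               f"recorded (min,max,mean,rms) = "
               f"({h['dmin']}, {h['dmax']}, {h['dmean']}, {h['rms']})")
    else:
        _check(checks, "statistics", h["mode"] == 4 or n_items == 0,
               "statistics not checkable")

    return MrcValidationReport(checks=checks)
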