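"""Optional, best-effort DICOM adapters (require ``pydicom``).

Only the geometry the pipeline needs is extracted: dwell positions/times
from an RT Plan's brachy application setups, and per-slice contours from
an RT Structure Set.  These adapters are convenience importers, not a
validated DICOM implementation; the package's native text dialects remain
the reference formats.
"""

from __future__ import annotations

import numpy as np

from .errors import PlanParseError
from .source import (DEFAULT_FRACTIONS, DEFAULT_PRESCRIPTION_GY,
                     DEFAULT_SK_U, DwellPlan)


def load_dicom_plan(source) -> DwellPlan:
    """Extract dwell positions (mm) and times (s) from an RT Plan dataset.

    ``source`` is a path or an open ``pydicom`` dataset.  Cumulative time
    weights of each brachy control-point sequence are converted to
    per-dwell times; channel total times scale the weights as in the
    standard RT Plan encoding.
    """
    import pydicom

    ds = source if hasattr(source, "get") else pydicom.dcmread(source)
    pos: list[list[float]] = []
    times: list[float] = []
    sk = DEFAULT_SK_U
    for app in ds.get("ApplicationSetupSequence", []):
        for chan in app.get("ChannelSequence", []):
            total = float(chan.get("ChannelTotalTime", 0.0))
            final_w = float(chan.get("FinalCumulativeTimeWeight", 0.0))
            cps = list(chan.get("BrachyControlPointSequence", []))
            prev_w = 0.0
            prev_pos = None
            for cp in cps:
                w = float(cp.get("CumulativeTimeWeight", 0.0))
                p = cp.get("ControlPoint3DPosition", None)
                if p is None:
                    continue
                p = [float(v) for v in p]
                if prev_pos is not None and p == prev_pos and w > prev_w:
                    dt = (w - prev_w) * (total / final_w if final_w else 1.0)
                    pos.append(p)
                    times.append(dt)
                prev_w, prev_pos = w, p
    for src in ds.get("SourceSequence", []):
        ref = src.get("ReferenceAirKermaRate", None)
        if ref is not None:
            sk = float(ref)
    if not times:
        raise PlanParseError("no dwells found in RT Plan dataset")
    return DwellPlan(np.array(pos), np.array(times),
                     air_kerma_strength=sk,
                     prescription_dose=DEFAULT_PRESCRIPTION_GY,
                     fractions=DEFAULT_FRACTIONS)


def load_dicom_structures(source) -> dict[str, list[tuple[float, np.ndarray]]]:
    """Extract per-slice (z, polygon) contours from an RT Structure Set."""
    import pydicom

    ds = source if hasattr(source, "get") else pydicom.dcmread(source)
    names = {}
    for roi in ds.get("StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)
    out: dict[str, list[tuple[float, np.ndarray]]] = {}
    for rc in ds.get("ROIContourSequence", []):
        name = names.get(int(rc.get("ReferencedROINumber", -1)), "?")
        for c in rc.get("ContourSequence", []):
            data = np.array([float(v) for v in c.ContourData])
            xyz = data.reshape(-1, 3)
            out.setdefault(name, []).append(
                (float(xyz[0, 2]), xyz[:, :2].copy()))
    return out
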