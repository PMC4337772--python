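"""Annotate a synthetic track with a field whose exact value is known.

Builds an affine environmental field f(lon, lat, t) = 2 + 0.5 lon +
0.25 lat + t_hours on a 1-degree / 6-hour grid, generates a short track,
annotates it with bilinear-in-space, linear-in-time interpolation, and
compares every annotated value to the closed form.
"""

import numpy as np

from envtrack import (AnnotationRequest, FieldSpec, TrackSpec,
                      VariableRequest, annotate_track, make_field, make_track)

var, f = make_field(FieldSpec(
    form="affine", params={"a": 2.0, "b": 0.5, "c": 0.25, "d": 1.0},
    x=(0.0, 1.0, 11), y=(0.0, 1.0, 11),
    times=[0.0, 21600.0, 43200.0], var_id="syn.affine"))

track = make_track(TrackSpec(waypoints=[(0.5, 0.5), (9.0, 8.0)],
                             speed_mps=60.0, fix_interval_s=5400.0))

request = AnnotationRequest(variables=[VariableRequest("syn.affine")])
annotated, log = annotate_track(track, request, {"syn.affine": var})

col = "syn.affine.bilinear-idw"
print(annotated[["timestamp", "location-long", "location-lat", col]].head(6))

from envtrack.annotator import track_epochs  # noqa: E402
errs = [abs(row[col] - f(row["location-long"], row["location-lat"], t))
        for (_, row), t in zip(annotated.iterrows(), track_epochs(annotated))]
print(f"\nmax |annotated - closed form| over {len(errs)} fixes: {max(errs):.2e}")
print("Bilinear + linear-in-time interpolation is exact for fields affine in")
print("(x, y, t), so this error is pure floating-point noise.")
print("run log:", log["columns"])
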