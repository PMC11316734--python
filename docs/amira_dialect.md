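# Spatial-graph file formats

## Amira HxSpatialGraph ASCII dialect

`retvasc` reads and writes spatial graphs as AmiraMesh 3D ASCII with the
`HxSpatialGraph` content type.  The dialect is fixed byte-exactly as
follows (the binary AmiraMesh variants are out of scope).

```
# AmiraMesh 3D ASCII 3.0
# retvasc spatial graph

define VERTEX <n_vertices>
define EDGE <n_edges>
define POINT <n_points>

Parameters {
    ContentType "HxSpatialGraph",
    Units { Coordinates "mm", Radius "um" },
    RetvascMetadata "<escaped JSON provenance>"
}

VERTEX { float[3] VertexCoordinates } @1
VERTEX { int NodeKind } @2
EDGE { int[2] EdgeConnectivity } @3
EDGE { int NumEdgePoints } @4
EDGE { int VesselClass } @5
POINT { float[3] EdgePointCoordinates } @6
POINT { float Radius } @7

@1
<x y z per vertex, %.9g>
...
```

Rules:

- Counts in the `define` lines are authoritative; a body block whose row
  count disagrees is a `count mismatch` error, non-numeric tokens are a
  `non-numeric payload` error, and a missing signature or `define` is a
  `malformed header` error.
- `@6`/`@7` list the per-edge point runs back to back in `@3` order; each
  edge's first and last point coincide with its two vertices.  `@4` row
  sums must equal `define POINT`.
- `NodeKind` codes: 0 inlet-root, 1 outlet-root, 2 bifurcation,
  3 terminal, 4 interior-path-point.  `VesselClass` codes: 0 artery,
  1 vein, 2 capillary.
- Coordinates are millimetres and radii micrometres, restated in the
  `Units` parameter; numbers are written with `%.9g`, so a write→read
  round trip preserves them to at least 6 significant figures (in practice
  9).
- Unknown data sections (any name not listed above) are parsed and kept in
  `VascularNetwork.metadata["amira_extra_fields"]`.
- `RetvascMetadata` carries the run provenance (seed, stage, parameter
  echo) as JSON with `"` escaped as `\"`.

## JSON network dialect (schema `retvasc-network`, version 1)

```json
{
  "schema": "retvasc-network",
  "schema_version": 1,
  "units": {"coordinates": "mm", "radius": "um"},
  "inlet_id": 0,
  "outlet_id": 2,
  "metadata": {"seed": 7, "stage": "connected"},
  "nodes": [{"id": 0, "position": [0, 0, -0.5], "kind": "inlet-root"}],
  "segments": [{"id": 0, "nodes": [0, 1],
                "path": [[0, 0, -0.5], [0, 0, 0]],
                "radii": [67.5, 67.5], "vessel_class": "artery"}]
}
```

Node ids and segment ids are preserved verbatim.  Flow tables and
time-course CSVs exported elsewhere in the package join on `segment_id`.
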