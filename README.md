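# tissuegraph

Attributed spatial cell-neighborhood graphs from segmented 2D/3D tissue
images.

Modern fluorescence microscopy produces multi-channel, multi-plane images of
tissues at sub-micron resolution, and segmentation tools (Cellpose and
friends) turn them into label masks — one unique positive integer per cell on
a zero background.  The pixel representation is bulky and awkward for
questions about *cells and their neighbors*: who touches whom, how many
neighbors does a cell of a given phenotype have, how does the tissue surface
differ from its core.  `tissuegraph` condenses a segmented image (or a cell
table from any upstream tool) into a **network twin** of the tissue: an
undirected graph whose nodes are cells carrying morphometric and
fluorescence attributes and whose edges are neighborhood relations.  The
graph is a plain `networkx.Graph`, so the whole graph-analysis ecosystem
applies downstream.

It is aimed at image-analysis practitioners in tissue biology — organoid /
spheroid phenotyping, neural stem-cell niche mapping, spatial phenotype
statistics — who already have segmentations and want quantitative
neighborhood read-outs without hand-rolling geometry code.

## The model

**Node attributes** (per cell mask, all in physical units): centroid
*x, y(, z)*; area (2D) or volume (3D); eccentricity and principal-axis
orientation from the second central moment matrix *C* of the member pixel
coordinates — with eigenvalues λ₁ ≥ … ≥ λ_d,

    eccentricity = √(1 − λ_d/λ₁),   major axis = λ₁ eigenvector,

which reduces to the classical ellipse eccentricity in 2D; and the mean
fluorescence per channel over the mask, with optional thresholding into
categorical cell types (mean > threshold ⇒ positive).

**Edge rules** — three ways to define "neighbors":

| rule | condition | edge attributes |
|---|---|---|
| geometric | 0 < ‖cᵢ − cⱼ‖ ≤ d_max | distance |
| delaunay | Delaunay 1-skeleton of centroids, edges > d_max removed | distance |
| contact | masks share ≥ 1 pixel face (4/6-connectivity) | distance, contact_size |

`contact_size` is the shared membrane length (2D) or area (3D), accumulated
per face orientation so anisotropic voxels are measured correctly.

**Analyses**: degree and link-length distributions; concentric **layer
peeling** (iterative convex-hull peeling of centroids, or
background-contact + hop distance on full-mask images) with per-layer degree
and link-length profiles; **same-type clusters** — connected components of
the subgraph induced by one phenotype — with the fraction of each type in
clusters of size ≥ 2.

A synthetic-tissue module generates rasterized Voronoi tessellations of
random generator points (the true adjacency is then the generator Delaunay
graph, by duality) and spheroid-like 3D point clouds, so every stage is
testable against known ground truth.

## Worked example

```python
import tissuegraph as tg

spec = tg.SyntheticTissueSpec(n_cells=30, shape=(512, 512), seed=1)
tissue = tg.generate_voronoi_tissue(spec)

table = tg.extract_cells(tissue.image)                       # per-cell attributes
table = tg.classify_by_threshold(table, "pcna", 6500, "PCNA+", "PCNA-")

graph, contacts = tg.build_contact_graph(tissue.image)       # membrane adjacency
tg.attach_node_attributes(graph, table)

deg = tg.degree_distribution(graph)
link = tg.link_length_distribution(graph)
print(f"{graph.number_of_nodes()} cells, {graph.number_of_edges()} links")
print(f"mean degree {deg.mean:.2f} +/- {deg.std:.2f}")
print(f"mean centre-to-centre distance {link.mean:.1f} +/- {link.std:.1f} um")
comp = tg.type_composition(table)
print("composition:", {t: round(f, 2) for t, f in sorted(comp.items())})
frac = tg.find_type_clusters(graph).fraction_clustered(min_size=2)
print("fraction in same-type clusters >= 2:", {t: round(f, 2) for t, f in sorted(frac.items())})
```

prints

```
30 cells, 70 links
mean degree 4.67 +/- 1.66
mean centre-to-centre distance 105.7 +/- 34.1 um
composition: {'PCNA+': 0.3, 'PCNA-': 0.7}
fraction in same-type clusters >= 2: {'PCNA+': 0.78, 'PCNA-': 1.0}
```

Thirty Voronoi cells tile the image, so the contact graph averages ~4.7
membrane neighbors per cell; cell intensities straddle the 6500 threshold,
so thresholding recovers the generator's 30/70 phenotype split; and every
"PCNA−" cell (the majority type) sits in a same-type cluster of at least
two, while the sparser "PCNA+" cells are clustered less often.

The same pipeline runs from a shell:

```bash
tissuegraph synth --n-cells 30 --seed 1 --outdir fixtures
tissuegraph build fixtures/tissue.tif --rule contact --threshold pcna=6500 \
    --layers background --outdir run1
tissuegraph analyze run1/graph.graphml --outdir run2   # cheap re-analysis
```

`build` writes `cells.csv`, `graph.graphml`, `contacts.csv`, per-node and
per-layer reports, and a `manifest.json` recording the resolved parameters.

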