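# nucleomech

Image quantification for nuclear mechanobiology assays, with a synthetic-data
generator so that every pipeline stage is verifiable offline by parameter
recovery.

Modules (under `src/nucleomech/`):

| module | what it does |
| --- | --- |
| `stacks`, `config`, `results` | TIFF image containers with physical metadata, key-value configuration with documented defaults, deterministic CSV/JSON serialization |
| `synth` | ground-truth generators: Brownian bead tracks and rendered movies, 15-channel (460–600 nm) emission stacks, truncated-exponential photon decays, nuclei with slit invaginations, polarized nuclear-signal cells, multichannel cell images, persistent-random-walk trajectories |
| `microrheology` | bead detection (subpixel intensity-weighted centroids), mutual-nearest-neighbour proximity linking, time-averaged MSD, diffusivity fits (`msd = 4·D·τ + b`) |
| `fret` | inverted FRET index: donor (~480 nm) / acceptor (~530 nm) emission-peak ratio per labeled nuclear-envelope region |
| `flim` | mono-exponential fluorescence lifetime by truncated-window maximum likelihood, pooled per region |
| `morphometry` | excess of perimeter (NE trace length over convex-envelope perimeter; exact polygon mode and rasterized skeleton mode), front-oriented polarity maps of top-quantile signal, front/rear symmetry test and condition-vs-condition Cramér–von Mises test |
| `cellquant` | nuclear/cytoplasmic ratio, dots-per-area, focal-adhesion count, actin structure-tensor coherency, spreading ratio |
| `motility` | nucleus tracking, mean speed, path persistence (directionality ratio), origin-centred trajectory tables |

## Command line

Every assay is a subcommand of `nucleomech`; all take `--seed`, `--out DIR`,
and optionally `--config FILE` (plain-text `assay.key = value` lines, unknown
keys rejected). Outputs are CSV tables plus a `summary.json` recording
parameters and seed; identical seed and config reproduce identical bytes.

```sh
nucleomech simulate brownian --seed 1 --out fix/            # synthetic fixture + groundtruth.json
nucleomech msd --tracks fix/tracks.csv --dt 0.01 --out out/ # MSD + diffusivity
nucleomech fret --stack spec.tif --mask ne.tif --out out/
nucleomech flim --decays decay.csv --out out/
nucleomech eop --outline outline.csv --out out/             # or --skeleton/--mask TIFFs
nucleomech polarity --manifest manifest.csv --out out/
nucleomech ncratio|dots|facount|coherency|spreading|motility ...
```

`simulate` fixtures: `brownian`, `movie`, `spectral`, `decay`, `nucleus`,
`polarized`, `cell`, `trajectories`; generator parameters are overridden with
`-p key=value`.

## Conventions

- Coordinates are 0-based pixels, arrays indexed `[row (y), col (x)]`;
  subpixel positions are continuous; physical units via `pixel_size_um`.
- The cell "front" is the +x direction in all polarity fixtures and maps.
- 8-connectivity for all connected-component labeling.
- All randomness flows from one per-invocation seed recorded in the output.
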