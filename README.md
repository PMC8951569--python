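# angiotrack

Dye-free coronary artery tracking in cine-angiograms.

A coronary angiographic acquisition contains at least one *dye-free*
cardiac cycle before contrast injection. `angiotrack` segments the
coronary tree in the contrasted frames (multi-scale Hessian vesselness +
morphological cleanup), detects the contrast-bolus window automatically,
and then estimates the vessel position in every dye-free frame by
associating it with the most similar contrasted "template" frame via
normalized cross-correlation and transferring that template's vessel
contour. A ground-truthed synthetic cine-angiogram simulator (branching
splined vessels, tapering widths, focal stenoses, periodic cardiac motion,
bolus wash-in/wash-out, noise) makes the whole pipeline testable without
patient data.

## Pipeline

1. **Load** a multi-frame DICOM (or a directory of single-frame DICOMs);
   intensities are min-max normalized *globally over the sequence* so the
   bolus dynamics survive. MONOCHROME1 data is inverted so vessels are
   always dark.
2. **Detect the bolus window**: per-frame vessel-pixel counts (vesselness →
   threshold → cleanup) form an opacity curve; the window is the longest
   run of frames above a fraction (default 0.3) of the curve maximum.
   The automatic window can be overridden per endpoint
   (`--contrast-start/--contrast-end`) — the automatic criterion is a
   design choice of this implementation, not a published rule.
3. **Build the template bank**: each window frame carries its vessel mask,
   traced contours, and a *background mask* (complement of the dilated
   vessel mask) so that matching compares dye-independent anatomy.
4. **Track**: each pre-injection frame is scored against every template by
   zero-lag Pearson cross-correlation (default region: background); the
   arg-max template lends its contour — this doubles as the cardiac-phase
   association.
5. **Render & report**: color overlays (predicted contours yellow,
   reference green), per-frame contour JSON, and a machine-readable run
   report.

## CLI

```sh
# generate a synthetic acquisition with ground truth
angiotrack simulate --preset stenosed --seed 1 -o sim/

# run the tracking pipeline (DICOM in, overlays + reports out)
angiotrack track sim/cine.dcm -o run/ [--config run.yaml] \
    [--contrast-start N --contrast-end M] [--detect-fraction F] \
    [--region full|background] [--include-postbolus]

# score the run against the simulation's ground truth
angiotrack evaluate run/run_report.json sim/ -o eval.json

# single-frame segmentation debug
angiotrack segment sim/cine.dcm --frame 30 -o seg/
```

All parameters (vesselness scales/sensitivities, thresholding, cleanup,
detection fraction, matching region, overlay style) live in an optional
YAML config with sections `segmentation:`, `detection:`, `matching:`,
`overlay:`; unknown keys are rejected. Phantom configs for `simulate
--config` mirror `PhantomConfig` (see `tests/test_config_cli.py` for a
worked example).

## Notes

- The DICOM codec is intentionally minimal: uncompressed Explicit/Implicit
  VR Little Endian grayscale only (no compressed syntaxes, no color, no
  biplane). It exists so the package has zero heavyweight I/O deps.
- Quantitative lumen measurement (QCA), calcium scoring, deformable
  registration, temporal smoothing of template assignments, and any GUI
  are explicitly out of scope.
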