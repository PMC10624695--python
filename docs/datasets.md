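# Public OCT datasets

The package's loader consumes either a per-class directory tree

    <root>/<class_name>/*.png|tif|jpg|bmp

or a CSV manifest with header `path,label,case_id`. The four public datasets
commonly used for retinal OCT classification can all be arranged this way
after download (none are fetched automatically):

| Dataset    | Device     | Classes typically used            | Source |
|------------|------------|-----------------------------------|--------|
| OCTID      | Cirrus HD  | NORMAL, MH, AMD, CSR, DR          | <https://doi.org/10.17632/fsm7tmzy7j> (Mendeley Data) |
| TOPCON / Isfahan | Topcon 3D OCT-1000 | Normal, DME          | distributed by the Isfahan MISP center |
| Duke       | Spectralis | AMD, DME, Normal                  | <https://people.duke.edu/~sf59/RPEDC_Ophth_2013_dataset.htm> |
| Heidelberg / Noor | Spectralis | AMD, DME, Normal           | distributed with the MCME study's data availability statement |

Practical notes:

- Scans within one dataset often differ in size; pass a resize policy
  (`--resize H W` on the CLI) so all images share one shape, or crop
  beforehand.
- If several B-scans come from the same eye/patient, fill the `case_id`
  column accordingly and split by case to avoid leakage; the default split
  is per-image.
- Grayscale conversion and [0, 1] scaling by bit-depth are automatic; no
  other pre-processing is applied.
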