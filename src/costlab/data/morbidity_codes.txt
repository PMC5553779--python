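# Morbidity classification catalog: 13 admission-morbidity categories with
# their ICD-9-CM and ICD-10-CA code patterns, one stanza per category.
# Syntax: "[Category Name]" on its own line, followed by comma-separated
# patterns. A pattern is an exact code ("416.8"), a wildcard stem ("401.x"),
# or an inclusive range ("430.x-438.x"); en-dash and ASCII hyphen are both
# accepted as the range separator.

[Hypertension]
401.x, 402.x, 403.x, 404.x, 405.x, I10.x, I11.x, I12.x, I13.x, I15.x

[Secondary Cerebrovascular Disease]
362.34, 430.x–438.x, G45.x, G46.x, H34.0, I60.x–I69.x

[Diabetes]
250.0–250.3, 250.4–250.7, 250.8, 250.9, E10.0–E10.9, E11.0–E11.9,
E12.0–E12.9, E13.0–E13.9, E14.0–E14.9

[Cardiac Disorders]
398.91, 402.01, 402.11, 402.91, 404.01, 404.03, 404.11, 404.13, 404.91,
404.93, 410.x, 412.x, 425.4–425.9, 428.x, I09.9, I11.0, I13.0, I13.2,
I25.5, I21.x, I22.x, I25.2, I42.0, I42.5–I42.9, I43.x, I50.x, P29.0

[Chronic Pulmonary Disease]
416.8, 416.9, 490.x–505.x, 506.4, 508.1, 508.8, I27.8, I27.9, J40.x–J47.x,
J60.x–J67.x, J68.4, J70.1, J70.3

[Malignancy or Tumour]
140.x–172.x, 174.x–195.8, 196.x–199.x, 200.x–208.x, 238.6, C00.x–C26.x,
C30.x–C34.x, C37.x–C41.x, C43.x, C45.x–C58.x, C60.x–C76.x, C77.x–C80.x,
C81.x–C85.x, C88.x, C90.x–C97.x

[Dementia]
290.x, 294.1, 331.2, F00.x–F03.x, F05.1, G30.x, G31.1

[Mood Disorders]
296.x, 311.x, F30.x, F31.x, F32.x, F33.x, F34.x, F38.x, F39.x

[Renal Disease]
403.01, 403.11, 403.91, 404.02, 404.03, 404.12, 404.13, 404.92, 404.93,
582.x, 583.0–583.7, 585.x, 586.x, 588.0, I12.0, I13.1, N03.2–N03.7,
N05.2–N05.7, N18.x, N19.x, N25.0, V42.0, V45.1, V56.x, Z49.0–Z49.2,
Z94.0, Z99.2

[Peripheral Vascular Disease]
093.0, 437.3, 440.x, 441.x, 443.1–443.9, 447.1, 557.1, 557.9, I70.x,
I71.x, I73.1, I73.8, I73.9, I77.1, I79.0, I79.2, K55.1, K55.8, K55.9,
V43.4, Z95.8, Z95.9

[Liver Disease]
070.22, 070.23, 070.32, 070.33, 070.44, 070.54, 070.6, 070.9, 456.0–456.2,
570.x, 571.x, 572.2–572.8, 573.3, 573.4, 573.8, 573.9, B18.x, I85.0,
I85.9, I86.4, I98.2, K70.0–K70.4, K70.9, K71.1, K72.1, K72.9, K76.5,
K76.6, K76.7, K71.3–K71.5, K71.7, K73.x, K74.x, K76.0, K76.2–K76.4,
K76.8, K76.9, V42.7, Z94.4

[Rheumatic Disease]
446.5, 710.0–710.4, 714.0–714.2, 714.8, 725.x, M05.x, M06.x, M31.5,
M32.x–M34.x, M35.1, M35.3, M36.0

[Peptic Ulcer Disease]
531.x–534.x, K25.x–K28.x
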