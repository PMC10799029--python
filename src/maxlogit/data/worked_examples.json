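{
  "format": "maxlogit-worked-examples-v1",
  "description": "Published per-sample worked examples: four-gene expression values, competing-factor scores, winning score (CFmax) and risk probability (Pmax), all preserved as printed (strings keep the displayed precision). Sample type 1 = tumor, 0 = control.",
  "gene_columns": ["APP", "CXCL8", "PSMC2", "SLC20A1"],
  "blocks": [
    {
      "dataset": 1,
      "cohort": "North American",
      "rows": [
        {"sample_id": "TCGA-AA-3522-110", "label": 0,
         "expression": {"APP": 14.46, "CXCL8": 2.57, "PSMC2": 10.12, "SLC20A1": 12.36},
         "cf": ["-4.05384", "-6.10284", null], "cf_max": "-4.05384", "p_max": "0.01706"},
        {"sample_id": "TCGA-AA-3518-110", "label": 0,
         "expression": {"APP": 14.71, "CXCL8": 2.84, "PSMC2": 9.95, "SLC20A1": 12.12},
         "cf": ["-4.08397", "-6.24816", null], "cf_max": "-4.08397", "p_max": "0.016562"},
        {"sample_id": "TCGA-DM-A1DA-011", "label": 1,
         "expression": {"APP": 13.32, "CXCL8": 5.64, "PSMC2": 10.92, "SLC20A1": 9.79},
         "cf": ["-0.68019", "0.829748", null], "cf_max": "0.829748", "p_max": "0.696302"},
        {"sample_id": "TCGA-AD-6965-011", "label": 1,
         "expression": {"APP": 14.11, "CXCL8": 5.66, "PSMC2": 11.10, "SLC20A1": 10.39},
         "cf": ["2.072846", "0.802252", null], "cf_max": "2.072846", "p_max": "0.888236"}
      ]
    },
    {
      "dataset": 2,
      "cohort": "North American",
      "rows": [
        {"sample_id": "TCGA-AA-3511-11A", "label": 0,
         "expression": {"APP": 7.865804, "CXCL8": 0.840519, "PSMC2": 4.230288, "SLC20A1": 3.752095},
         "cf": ["-1.66003", "-1.22637", null], "cf_max": "-1.22637", "p_max": "0.226818"},
        {"sample_id": "TCGA-AA-3517-11A", "label": 0,
         "expression": {"APP": 7.346597, "CXCL8": 0.735178, "PSMC2": 4.032976, "SLC20A1": 6.230919},
         "cf": ["-9.56825", "-9.26049", null], "cf_max": "-9.26049", "p_max": "9.51E-05"},
        {"sample_id": "TCGA-AZ-4323-01A", "label": 1,
         "expression": {"APP": 6.716108, "CXCL8": 5.586939, "PSMC2": 4.427988, "SLC20A1": 3.826772},
         "cf": ["4.067608", "4.417109", null], "cf_max": "4.417109", "p_max": "0.988075"},
        {"sample_id": "TCGA-AA-3971-01A", "label": 1,
         "expression": {"APP": 7.566649, "CXCL8": 4.029144, "PSMC2": 5.304325, "SLC20A1": 3.394695},
         "cf": ["5.079653", "8.352782", null], "cf_max": "8.352782", "p_max": "0.999764"}
      ]
    },
    {
      "dataset": 3,
      "cohort": "European",
      "rows": [
        {"sample_id": "13530", "label": 0,
         "expression": {"APP": 10.90443, "CXCL8": 4.798452, "PSMC2": 9.339269, "SLC20A1": 9.580673},
         "cf": ["-1.15919", "-5.59369", "-9.92037"], "cf_max": "-1.15919", "p_max": "0.238814"},
        {"sample_id": "13540", "label": 0,
         "expression": {"APP": 10.95167, "CXCL8": 8.181189, "PSMC2": 9.176233, "SLC20A1": 9.897567},
         "cf": ["-1.91304", "-6.76058", "-0.59102"], "cf_max": "-0.59102", "p_max": "0.356402"},
        {"sample_id": "19611", "label": 1,
         "expression": {"APP": 11.19171, "CXCL8": 9.436294, "PSMC2": 10.13665, "SLC20A1": 9.334996},
         "cf": ["1.29651", "-2.77754", "11.05611"], "cf_max": "11.05611", "p_max": "0.999984"},
        {"sample_id": "19621", "label": 1,
         "expression": {"APP": 11.05174, "CXCL8": 11.19743, "PSMC2": 10.72173, "SLC20A1": 9.063379},
         "cf": ["2.788005", "-3.349192", "21.23988"], "cf_max": "21.23988", "p_max": "1"}
      ]
    },
    {
      "dataset": 7,
      "cohort": "Independent Chinese",
      "rows": [
        {"sample_id": "1359 T", "label": 1,
         "expression": {"APP": 1.81, "CXCL8": 4.63, "PSMC2": 0.82, "SLC20A1": 0.35},
         "cf": ["-2.54", "0.03", "8.46"], "cf_max": "8.46", "p_max": "1"},
        {"sample_id": "1360 T", "label": 1,
         "expression": {"APP": 0.95, "CXCL8": 5.1, "PSMC2": 0.91, "SLC20A1": 0.44},
         "cf": ["-1.17", "-0.01", "11.28"], "cf_max": "11.28", "p_max": "1"},
        {"sample_id": "1368 N", "label": 0,
         "expression": {"APP": 0.45, "CXCL8": 0.2, "PSMC2": 1.4, "SLC20A1": 3.19},
         "cf": ["-0.51", "-3.92", "-2.15"], "cf_max": "-0.51", "p_max": "0.38"},
        {"sample_id": "1369 N", "label": 0,
         "expression": {"APP": 2.68, "CXCL8": 0.23, "PSMC2": 0.71, "SLC20A1": 0.98},
         "cf": ["-3.93", "-1.16", "-5.79"], "cf_max": "-1.16", "p_max": "0.24"}
      ]
    }
  ]
}
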