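{
  "description": "Reference ligament material parameters per constitutive model. Spring and FRPHE carry 'initial' literature-based values and 'adjusted' values obtained by matching the first peak of the tibiofemoral reaction force across models.",
  "ligaments": ["ACL", "PCL", "MCL", "LCL", "PT", "QT"],
  "spring": {
    "units": "N/mm",
    "initial": {"ACL": 201, "PCL": 258, "MCL": 114, "LCL": 134, "PT": 545, "QT": 475},
    "adjusted": {"ACL": 100, "PCL": 129, "MCL": 57, "LCL": 67, "PT": 545, "QT": 475}
  },
  "linear": {
    "E_MPa": {"ACL": 123, "PCL": 168, "MCL": 224, "LCL": 280, "PT": 336, "QT": 370},
    "nu": {"ACL": 0.4, "PCL": 0.4, "MCL": 0.4, "LCL": 0.4, "PT": 0.4, "QT": 0.4}
  },
  "neohookean": {
    "C1_MPa": {"ACL": 22, "PCL": 30, "MCL": 40, "LCL": 50, "PT": 60, "QT": 66},
    "D_per_MPa": {"ACL": 0.005, "PCL": 0.0036, "MCL": 0.003, "LCL": 0.0021, "PT": 0.002, "QT": 0.002}
  },
  "poro": {
    "C1_MPa": {"ACL": 22, "PCL": 30, "MCL": 40, "LCL": 50, "PT": 60, "QT": 66},
    "D_per_MPa": {"ACL": 0.005, "PCL": 0.0036, "MCL": 0.003, "LCL": 0.0021, "PT": 0.002, "QT": 0.002},
    "k0_1e-15_m4_per_Ns": {"ACL": 2.9, "PCL": 2.9, "MCL": 2.9, "LCL": 2.9, "PT": 2.9, "QT": 2.9},
    "M": {"ACL": 7.98, "PCL": 7.98, "MCL": 7.98, "LCL": 7.98, "PT": 7.98, "QT": 7.98}
  },
  "frphe": {
    "Ef_MPa_initial": {"ACL": 130, "PCL": 180, "MCL": 270, "LCL": 280, "PT": 184, "QT": 380},
    "Ef_MPa_adjusted": {"ACL": 100, "PCL": 40, "MCL": 120, "LCL": 100, "PT": 150, "QT": 150},
    "Em_MPa": {"ACL": 1, "PCL": 1, "MCL": 1, "LCL": 1, "PT": 10, "QT": 10},
    "nu_m": {"ACL": 0.4, "PCL": 0.4, "MCL": 0.4, "LCL": 0.4, "PT": 0.4, "QT": 0.4},
    "k0_1e-15_m4_per_Ns": {"ACL": 2.9, "PCL": 2.9, "MCL": 2.9, "LCL": 2.9, "PT": 2.9, "QT": 2.9},
    "M": {"ACL": 7.98, "PCL": 7.98, "MCL": 7.98, "LCL": 7.98, "PT": 7.98, "QT": 7.98},
    "C": {"ACL": 12, "PCL": 12, "MCL": 2, "LCL": 2, "PT": 2, "QT": 2}
  },
  "patellofemoral": {
    "note": "MPFL and LPFL are elastic truss elements",
    "E_MPa": 19,
    "nu": 0.499
  },
  "rsd": {"ACL": 0.62, "PCL": 0.60, "LCL": 0.70, "MCL": 0.71, "PT": 0.52, "QT": 0.43}
}
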