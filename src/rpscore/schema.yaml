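# Cohort CSV column dictionary.
schema_version: 1
columns:
- {name: id, unit: "-", kind: identifier, epoch: none}
- {name: distance_anal_verge, unit: "cm", kind: continuous, epoch: clinical}
- {name: cea, unit: "ng/mL", kind: continuous, epoch: clinical}
- {name: tumor_grade, unit: "ordinal 1-3", kind: categorical, epoch: clinical}
- {name: age, unit: "years", kind: continuous, epoch: clinical}
- {name: sex, unit: "0=female,1=male", kind: categorical, epoch: clinical}
- {name: clinical_T, unit: "ordinal 1-4", kind: categorical, epoch: clinical}
- {name: clinical_N, unit: "ordinal 0-2", kind: categorical, epoch: clinical}
- {name: pre_RBC, unit: "10^6/uL", kind: continuous, epoch: pre}
- {name: pre_HB, unit: "g/dL", kind: continuous, epoch: pre}
- {name: pre_Hct, unit: "%", kind: continuous, epoch: pre}
- {name: pre_MCV, unit: "fL", kind: continuous, epoch: pre}
- {name: pre_MCH, unit: "pg", kind: continuous, epoch: pre}
- {name: pre_MCHC, unit: "g/dL", kind: continuous, epoch: pre}
- {name: pre_RDW, unit: "%", kind: continuous, epoch: pre}
- {name: pre_PLT, unit: "10^3/uL", kind: continuous, epoch: pre}
- {name: pre_PCT, unit: "%", kind: continuous, epoch: pre}
- {name: pre_MPV, unit: "fL", kind: continuous, epoch: pre}
- {name: pre_PDW, unit: "%", kind: continuous, epoch: pre}
- {name: pre_WBC, unit: "cells/uL", kind: continuous, epoch: pre}
- {name: pre_neutrophil, unit: "cells/uL", kind: continuous, epoch: pre}
- {name: pre_lymphocyte, unit: "cells/uL", kind: continuous, epoch: pre}
- {name: pre_monocyte, unit: "cells/uL", kind: continuous, epoch: pre}
- {name: pre_eosinophil, unit: "cells/uL", kind: continuous, epoch: pre}
- {name: pre_basophil, unit: "cells/uL", kind: continuous, epoch: pre}
- {name: pre_calcium, unit: "mg/dL", kind: continuous, epoch: pre}
- {name: pre_phosphorus, unit: "mg/dL", kind: continuous, epoch: pre}
- {name: pre_glucose, unit: "mg/dL", kind: continuous, epoch: pre}
- {name: pre_uric_acid, unit: "mg/dL", kind: continuous, epoch: pre}
- {name: pre_cholesterol, unit: "mg/dL", kind: continuous, epoch: pre}
- {name: pre_total_protein, unit: "g/dL", kind: continuous, epoch: pre}
- {name: pre_albumin, unit: "g/dL", kind: continuous, epoch: pre}
- {name: pre_total_bilirubin, unit: "mg/dL", kind: continuous, epoch: pre}
- {name: pre_AST, unit: "U/L", kind: continuous, epoch: pre}
- {name: pre_ALT, unit: "U/L", kind: continuous, epoch: pre}
- {name: pre_ALP, unit: "U/L", kind: continuous, epoch: pre}
- {name: pre_creatinine, unit: "mg/dL", kind: continuous, epoch: pre}
- {name: early_RBC, unit: "10^6/uL", kind: continuous, epoch: early}
- {name: early_HB, unit: "g/dL", kind: continuous, epoch: early}
- {name: early_Hct, unit: "%", kind: continuous, epoch: early}
- {name: early_MCV, unit: "fL", kind: continuous, epoch: early}
- {name: early_MCH, unit: "pg", kind: continuous, epoch: early}
- {name: early_MCHC, unit: "g/dL", kind: continuous, epoch: early}
- {name: early_RDW, unit: "%", kind: continuous, epoch: early}
- {name: early_PLT, unit: "10^3/uL", kind: continuous, epoch: early}
- {name: early_PCT, unit: "%", kind: continuous, epoch: early}
- {name: early_MPV, unit: "fL", kind: continuous, epoch: early}
- {name: early_PDW, unit: "%", kind: continuous, epoch: early}
- {name: early_WBC, unit: "cells/uL", kind: continuous, epoch: early}
- {name: early_neutrophil, unit: "cells/uL", kind: continuous, epoch: early}
- {name: early_lymphocyte, unit: "cells/uL", kind: continuous, epoch: early}
- {name: early_monocyte, unit: "cells/uL", kind: continuous, epoch: early}
- {name: early_eosinophil, unit: "cells/uL", kind: continuous, epoch: early}
- {name: early_basophil, unit: "cells/uL", kind: continuous, epoch: early}
- {name: trg, unit: "ordinal 0-3", kind: outcome, epoch: outcome}
- {name: ypT, unit: "ordinal 0-4", kind: outcome, epoch: outcome}
- {name: ypN, unit: "ordinal 0-2", kind: outcome, epoch: outcome}
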