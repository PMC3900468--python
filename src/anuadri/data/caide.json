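{
  "name": "caide",
  "metadata": {
    "description": "CAIDE midlife dementia risk score used as a comparator index. Category weights follow the original CAIDE publication (Kivipelto et al., Lancet Neurol 2006); they are bundled configuration, not re-derived, and can be overridden.",
    "source": "Kivipelto M et al. Risk score for the prediction of dementia risk in 20 years among middle aged people. Lancet Neurol 2006;5:735-41.",
    "notes": "The sex point is assigned to men in the source publication. Education bands are the source's <7 / 7-9 / >=10 years."
  },
  "factors": [
    {
      "name": "caide_age",
      "stratified_by_sex": false,
      "derived_from": "age",
      "categories": [
        {"label": "<47", "points": 0, "age_min": 0, "age_max": 46},
        {"label": "47-53", "points": 3, "age_min": 47, "age_max": 53},
        {"label": ">53", "points": 4, "age_min": 54, "age_max": 200}
      ]
    },
    {
      "name": "sex",
      "stratified_by_sex": false,
      "derived_from": "sex",
      "categories": [
        {"label": "female", "points": 0},
        {"label": "male", "points": 1}
      ]
    },
    {
      "name": "caide_education",
      "stratified_by_sex": false,
      "categories": [
        {"label": ">=10", "points": 0},
        {"label": "7-9", "points": 2},
        {"label": "<7", "points": 3}
      ]
    },
    {
      "name": "systolic_bp",
      "stratified_by_sex": false,
      "categories": [
        {"label": "normal", "points": 0},
        {"label": "high", "points": 2}
      ]
    },
    {
      "name": "bmi",
      "stratified_by_sex": false,
      "categories": [
        {"label": "normal", "points": 0},
        {"label": "obese", "points": 2}
      ]
    },
    {
      "name": "cholesterol",
      "stratified_by_sex": false,
      "categories": [
        {"label": "normal", "points": 0},
        {"label": "high", "points": 2}
      ]
    },
    {
      "name": "caide_physical_activity",
      "stratified_by_sex": false,
      "categories": [
        {"label": "active", "points": 0},
        {"label": "inactive", "points": 1}
      ]
    }
  ]
}
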