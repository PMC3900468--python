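{
  "name": "anu_adri_full",
  "metadata": {
    "description": "ANU-ADRI published point table: integer points per risk/protective factor category; age points are sex-stratified. Protective categories carry negative points.",
    "notes": "The 'heavy' alcohol category carries no published points and defaults to 0 (overridable)."
  },
  "factors": [
    {
      "name": "age",
      "stratified_by_sex": true,
      "derived_from": "age",
      "categories": {
        "male": [
          {"label": "<65", "points": 0, "age_min": 0, "age_max": 64},
          {"label": "65-69", "points": 1, "age_min": 65, "age_max": 69},
          {"label": "70-74", "points": 12, "age_min": 70, "age_max": 74},
          {"label": "75-79", "points": 18, "age_min": 75, "age_max": 79},
          {"label": "80-84", "points": 26, "age_min": 80, "age_max": 84},
          {"label": "85-89", "points": 33, "age_min": 85, "age_max": 89},
          {"label": ">=90", "points": 38, "age_min": 90, "age_max": 200}
        ],
        "female": [
          {"label": "<65", "points": 0, "age_min": 0, "age_max": 64},
          {"label": "65-69", "points": 5, "age_min": 65, "age_max": 69},
          {"label": "70-74", "points": 14, "age_min": 70, "age_max": 74},
          {"label": "75-79", "points": 21, "age_min": 75, "age_max": 79},
          {"label": "80-84", "points": 29, "age_min": 80, "age_max": 84},
          {"label": "85-89", "points": 35, "age_min": 85, "age_max": 89},
          {"label": ">=90", "points": 41, "age_min": 90, "age_max": 200}
        ]
      }
    },
    {
      "name": "education",
      "stratified_by_sex": false,
      "categories": [
        {"label": "<8", "points": 0},
        {"label": "8-11", "points": 3},
        {"label": ">11", "points": 6}
      ]
    },
    {
      "name": "diabetes",
      "stratified_by_sex": false,
      "categories": [
        {"label": "no", "points": 0},
        {"label": "yes", "points": 3}
      ]
    },
    {
      "name": "tbi",
      "stratified_by_sex": false,
      "categories": [
        {"label": "no", "points": 0},
        {"label": "yes", "points": 4}
      ]
    },
    {
      "name": "depressive_symptoms",
      "stratified_by_sex": false,
      "categories": [
        {"label": "no", "points": 0},
        {"label": "yes", "points": 2}
      ]
    },
    {
      "name": "cognitive_activity",
      "stratified_by_sex": false,
      "categories": [
        {"label": "low", "points": 0},
        {"label": "moderate", "points": -6},
        {"label": "high", "points": -7}
      ]
    },
    {
      "name": "social_network",
      "stratified_by_sex": false,
      "categories": [
        {"label": "high", "points": 0},
        {"label": "medium_high", "points": 1},
        {"label": "medium_low", "points": 4},
        {"label": "low", "points": 6}
      ]
    },
    {
      "name": "smoking",
      "stratified_by_sex": false,
      "categories": [
        {"label": "never", "points": 0},
        {"label": "former", "points": 1},
        {"label": "current", "points": 4}
      ]
    },
    {
      "name": "alcohol",
      "stratified_by_sex": false,
      "categories": [
        {"label": "abstainer", "points": 0},
        {"label": "light_moderate", "points": -3},
        {"label": "heavy", "points": 0}
      ]
    },
    {
      "name": "physical_activity",
      "stratified_by_sex": false,
      "categories": [
        {"label": "low", "points": 0},
        {"label": "medium", "points": -2},
        {"label": "high", "points": -3}
      ]
    },
    {
      "name": "fish_intake",
      "stratified_by_sex": false,
      "categories": [
        {"label": "0-0.25", "points": 0},
        {"label": "0.26-2", "points": -3},
        {"label": "2.1-4", "points": -4},
        {"label": ">=4.1", "points": -5}
      ]
    }
  ]
}
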