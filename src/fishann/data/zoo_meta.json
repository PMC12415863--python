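{
  "dose_ranges_uL_per_L": {
    "common_carp": [800, 1400],
    "danube_sturgeon": [500, 1000],
    "rainbow_trout": [400, 800]
  },
  "entries": [
    {
      "species": "common_carp", "endpoint": "IT", "architecture": "1-10-1",
      "hidden_activation": "purelin", "trainer": "traingda",
      "output_bias": "0.0162", "bias_label": "theta_11", "caveats": []
    },
    {
      "species": "common_carp", "endpoint": "RT", "architecture": "1-10-1",
      "hidden_activation": "purelin", "trainer": "traingda",
      "output_bias": "13.8936", "bias_label": "theta_11",
      "caveats": [
        "weight block printed without an endpoint label; assigned to RT by the narrative architecture statement (1-10-1, purelin-purelin, traingda)",
        "printed output bias 13.8936 coincides with the HGB block's bias"
      ]
    },
    {
      "species": "common_carp", "endpoint": "WBC", "architecture": "1-6-1",
      "hidden_activation": "purelin", "trainer": "trainrp",
      "output_bias": "10.3895", "bias_label": "theta_7", "caveats": []
    },
    {
      "species": "common_carp", "endpoint": "RBC", "architecture": "1-7-1",
      "hidden_activation": "tansig", "trainer": "traingda",
      "output_bias": "-0.0054", "bias_label": "theta_8",
      "caveats": [
        "trainer printed as 'trainsgd', which the narrative expands to gradient descent with adaptive learning rate; treated as traingda"
      ]
    },
    {
      "species": "common_carp", "endpoint": "HGB", "architecture": "1-5-1",
      "hidden_activation": "logsig", "trainer": "trains",
      "output_bias": "13.8936", "bias_label": "theta_6", "caveats": []
    },
    {
      "species": "common_carp", "endpoint": "HCT", "architecture": "1-7-1",
      "hidden_activation": "tansig", "trainer": "traingda",
      "output_bias": "0.0280", "bias_label": "theta_8",
      "caveats": [
        "text says 1-7-1, table block has 8 rows",
        "weight block labeled 'RBC' in print (second RBC label); assigned to HCT by the narrative text",
        "printed bias header theta_8 agrees with the stated 1-7-1, not with the 8 printed rows"
      ]
    },
    {
      "species": "danube_sturgeon", "endpoint": "IT", "architecture": "1-10-1",
      "hidden_activation": "logsig", "trainer": "traingda",
      "output_bias": "87.513", "bias_label": "theta_11",
      "caveats": [
        "very large printed weights (e.g. W1[1] = -2718.79) are inconsistent with [0,1]-normalized inputs; input scale unverified"
      ]
    },
    {
      "species": "danube_sturgeon", "endpoint": "RT", "architecture": "1-8-1",
      "hidden_activation": "tansig", "trainer": "traingda",
      "output_bias": "50.091", "bias_label": "theta_9", "caveats": []
    },
    {
      "species": "danube_sturgeon", "endpoint": "WBC", "architecture": "1-7-1",
      "hidden_activation": "purelin", "trainer": "traingda",
      "output_bias": "11.457", "bias_label": "theta_8", "caveats": []
    },
    {
      "species": "danube_sturgeon", "endpoint": "RBC", "architecture": "1-5-1",
      "hidden_activation": "tansig", "trainer": "traingda",
      "output_bias": "-0.0156", "bias_label": "theta_6", "caveats": []
    },
    {
      "species": "danube_sturgeon", "endpoint": "HGB", "architecture": "1-7-1",
      "hidden_activation": "purelin", "trainer": "trains",
      "output_bias": "4.964", "bias_label": "theta_8",
      "caveats": [
        "rows 1-5 coincide with the common carp HGB block at reduced precision, as printed"
      ]
    },
    {
      "species": "danube_sturgeon", "endpoint": "HCT", "architecture": "1-10-1",
      "hidden_activation": "tansig", "trainer": "traingda",
      "output_bias": "0.019", "bias_label": "theta_11",
      "caveats": [
        "weight block labeled 'RBC' in print (second RBC label); assigned to HCT by the narrative text"
      ]
    },
    {
      "species": "rainbow_trout", "endpoint": "IT", "architecture": "1-8-1",
      "hidden_activation": "tansig", "trainer": "trains",
      "output_bias": "3.344", "bias_label": "theta_9",
      "caveats": [
        "row i=3 absent from printed table; 7 rows vs. stated 1-8-1; packaged with the 7 printed neurons, no invented parameters"
      ]
    },
    {
      "species": "rainbow_trout", "endpoint": "RT", "architecture": "1-6-1",
      "hidden_activation": "tansig", "trainer": "traingda",
      "output_bias": "27.481", "bias_label": "theta_7", "caveats": []
    },
    {
      "species": "rainbow_trout", "endpoint": "WBC", "architecture": "1-5-1",
      "hidden_activation": "purelin", "trainer": "traingda",
      "output_bias": "0.883", "bias_label": "theta_6", "caveats": []
    },
    {
      "species": "rainbow_trout", "endpoint": "RBC", "architecture": "1-4-1",
      "hidden_activation": "logsig", "trainer": "traingda",
      "output_bias": "-0.642", "bias_label": "theta_5", "caveats": []
    },
    {
      "species": "rainbow_trout", "endpoint": "HGB", "architecture": "1-10-1",
      "hidden_activation": "tansig", "trainer": "trains",
      "output_bias": "0.064", "bias_label": "theta_11",
      "caveats": [
        "rows 8 and 9 identical as printed"
      ]
    },
    {
      "species": "rainbow_trout", "endpoint": "HCT", "architecture": "1-8-1",
      "hidden_activation": "logsig", "trainer": "traingda",
      "output_bias": "0.028", "bias_label": "theta_9",
      "caveats": [
        "weight block labeled 'RBC' in print (second RBC label); assigned to HCT by the narrative text"
      ]
    }
  ]
}
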