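{
  "1": "F1", "2": "F1", "3": "F1", "4": "F1", "5": "F1",
  "6": "F1", "7": "F1", "8": "F1", "9": "F1", "10": "F1",
  "11": "F2", "12": "F2", "13": "F2", "14": "F2", "15": "F2",
  "16": "F2", "17": "F2", "18": "F2", "19": "F2", "20": "F2",
  "21": "F2",
  "22": "F3", "23": "F3", "24": "F3", "25": "F3", "26": "F3",
  "27": "F3", "28": "F3", "29": "F3",
  "30": "F4", "31": "F4", "32": "F4", "33": "F4", "34": "F4"
}
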