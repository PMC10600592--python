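year,facility,count
2022,King Fahad Hospital,73
2022,Prince Saud Bin Jalawi Hospital,9
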