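((Marchantia:410,(Sphagnum:300,(Physcomitrella:150,Ceratodon:150):150):110):65,(((Lycopodium:200,Huperzia:200):220,((I_coromandelina:50,((I_lacustris:20,I_echinospora:20):20,(I_engelmannii:25,(I_drummondii:15,I_histrix:15):10):15):10):350,(S_moellendorffii:120,(S_kraussiana:100,(S_uncinata:60,S_apoda:60):40):20):280):20):20,((Equisetum:300,(Psilotum:250,(Osmunda:200,(Pteridium:120,(Azolla:80,Salvinia:80):40):80):50):50):130,((Cycas:250,(Ginkgo:200,(Pinus:150,Gnetum:150):50):50):80,(Amborella:200,((Oryza:100,Ananas:100):60,((Arabidopsis:110,Theobroma:110):30,Ceratophyllum:140):20):40):130):100):10):35);
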