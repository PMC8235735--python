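label,hex,hexnac,fuc,neuac
Man5,5,2,0,0
Man6,6,2,0,0
Man7,7,2,0,0
Man8,8,2,0,0
Man9,9,2,0,0
Hex3HexNAc3,3,3,0,0
Hex3HexNAc4,3,4,0,0
Hex4HexNAc3,4,3,0,0
Hex4HexNAc4,4,4,0,0
Hex5HexNAc4,5,4,0,0
Hex6HexNAc5,6,5,0,0
Hex3HexNAc3Fuc1,3,3,1,0
Hex4HexNAc3Fuc1,4,3,1,0
Hex4HexNAc4Fuc1,4,4,1,0
Hex5HexNAc4Fuc1,5,4,1,0
Hex6HexNAc5Fuc1,6,5,1,0
Hex4HexNAc3NeuAc1,4,3,0,1
Hex4HexNAc4NeuAc1,4,4,0,1
Hex5HexNAc4NeuAc1,5,4,0,1
Hex6HexNAc4NeuAc1,6,4,0,1
Hex5HexNAc4NeuAc2,5,4,0,2
Hex6HexNAc4NeuAc2,6,4,0,2
Hex6HexNAc5NeuAc1,6,5,0,1
Hex6HexNAc5NeuAc2,6,5,0,2
Hex6HexNAc5NeuAc3,6,5,0,3
Hex7HexNAc6NeuAc2,7,6,0,2
Hex7HexNAc6NeuAc3,7,6,0,3
Hex7HexNAc6NeuAc4,7,6,0,4
Hex4HexNAc3Fuc1NeuAc1,4,3,1,1
Hex5HexNAc4Fuc1NeuAc1,5,4,1,1
Hex5HexNAc4Fuc1NeuAc2,5,4,1,2
Hex5HexNAc4Fuc1NeuAc3,5,4,1,3
Hex6HexNAc4Fuc1NeuAc2,6,4,1,2
Hex6HexNAc5Fuc1NeuAc1,6,5,1,1
Hex6HexNAc5Fuc1NeuAc2,6,5,1,2
Hex6HexNAc5Fuc1NeuAc3,6,5,1,3
Hex6HexNAc5Fuc2NeuAc3,6,5,2,3
Hex6HexNAc5Fuc1NeuAc4,6,5,1,4
Hex7HexNAc6Fuc1NeuAc2,7,6,1,2
Hex7HexNAc6Fuc1NeuAc3,7,6,1,3
Hex7HexNAc6Fuc1NeuAc4,7,6,1,4
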