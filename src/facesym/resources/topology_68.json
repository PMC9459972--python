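{"mode":"compact_68","pairs":[[0,1],[2,3],[4,5],[6,7],[8,9],[11,12],[13,14],[15,16],[19,20],[21,22],[25,26],[27,28],[29,30],[31,32],[33,34],[35,36],[42,43],[44,45],[46,47],[48,49],[50,51],[52,53],[54,55],[56,57],[58,59],[60,61],[62,63],[64,65],[66,67]],"midline":[10,17,18,23,24,37,38,39,40,41],"iris":{"left":35,"right":36},"muscle_groups":[{"id":1,"name":"Frontalis","indices":[]},{"id":2,"name":"Corrugator","indices":[]},{"id":3,"name":"Procerus","indices":[0,1]},{"id":4,"name":"Orbicularis Oculi","indices":[2,3,4,5,6,7]},{"id":5,"name":"Levator Labii Superioris","indices":[]},{"id":6,"name":"Nasalis","indices":[8,9]},{"id":7,"name":"Nose Tip","indices":[10,11,12]},{"id":8,"name":"Orbicularis Oris","indices":[13,14,15,16,17,18,19,20,21,22,23,24]},{"id":9,"name":"Mentalis","indices":[]},{"id":10,"name":"Depressor Anguli Oris","indices":[25,26]},{"id":11,"name":"Zygomaticus Minor","indices":[]},{"id":12,"name":"Zygomaticus Major","indices":[]},{"id":13,"name":"Buccinator","indices":[]},{"id":14,"name":"Risorius","indices":[]},{"id":15,"name":"Platysma","indices":[27,28]},{"id":16,"name":"Masseter","indices":[29,30,31,32]},{"id":17,"name":"Temporalis","indices":[33]}]}
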